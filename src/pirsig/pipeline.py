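"""Orchestration of the full signature workflow.

reference -> (optional simulation) -> differential expression per cell type
-> deregulation calls -> origin enrichment -> positional composition ->
TOP-N clustering -> cross-stage memory fractions and direction-stratified
overlaps, written as a diff-able TSV bundle with a machine-readable manifest.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, config_as_dict
from .de import (
    DECall,
    DesignSpec,
    call_deregulated,
    log_transform,
    nb_wald,
    size_factors,
    top_abundant_de,
    top_de,
    write_de_results,
)
from .quantify import CountMatrix, read_sample_sheet, write_sample_sheet
from .reference import (
    canonical_fraction,
    load_reference,
    origin_proportions,
    snorna_overlap,
    u1_fraction,
    write_fasta,
)
from .signature import composition_bias, direction_overlap, hcluster, memory_fraction
from .signature import origin_enrichment
from .simulate import (
    scenario as make_scenario,
    simulate_dataset,
    simulate_memory_pair,
    write_annotation,
    write_truth,
)

logger = logging.getLogger("pirsig")


@dataclass
class RunResult:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    de_results: dict[str, pd.DataFrame] = field(default_factory=dict)
    calls: dict[str, DECall] = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path, result: RunResult, header_comment: str = "") -> None:
    with open(path, "wt") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")
    result.files.append(path)


def _simulate_inputs(config: RunConfig, inputs_dir: Path, result: RunResult) -> None:
    """Generate scenario inputs on disk so the run exercises the file contracts."""
    params = make_scenario(config.scenario, seed=config.seed)
    inputs_dir.mkdir(parents=True, exist_ok=True)
    if config.scenario == "differentiation":
        pair = simulate_memory_pair(params)
        ref = pair.ref
        counts = pd.concat(
            [pair.stages[s].counts.counts for s in sorted(pair.stages)], axis=1
        )
        sheet = pd.concat([pair.stages[s].sheet for s in sorted(pair.stages)], axis=0)
        truth = pd.concat(
            {s: pair.stages[s].truth for s in sorted(pair.stages)}, names=["stage"]
        )
        CountMatrix(counts).to_tsv(inputs_dir / "counts.tsv")
        write_truth(truth.reset_index("stage"), inputs_dir / "truth.tsv")
    else:
        ds = simulate_dataset(params)
        ref, sheet = ds.ref, ds.sheet
        ds.counts.to_tsv(inputs_dir / "counts.tsv")
        write_truth(ds.truth, inputs_dir / "truth.tsv")
    write_fasta(ref, inputs_dir / "reference.fasta")
    write_annotation(ref, inputs_dir / "annotation.tsv")
    write_sample_sheet(sheet, inputs_dir / "samples.tsv")
    result.files += [
        inputs_dir / n
        for n in ("counts.tsv", "truth.tsv", "reference.fasta", "annotation.tsv", "samples.tsv")
    ]
    config.reference = inputs_dir / "reference.fasta"
    config.annotation = inputs_dir / "annotation.tsv"
    config.counts = inputs_dir / "counts.tsv"
    config.sample_sheet = inputs_dir / "samples.tsv"


def _usable_covariates(sheet: pd.DataFrame, wanted: tuple[str, ...]) -> tuple[str, ...]:
    """Keep covariates that exist and vary within this sample subset."""
    out = []
    for cov in wanted:
        if cov not in sheet.columns:
            logger.warning("covariate %r not in sample sheet; skipped", cov)
            continue
        if sheet[cov].nunique(dropna=False) < 2:
            logger.info("covariate %r constant in this subset; skipped", cov)
            continue
        out.append(cov)
    return tuple(out)


def run_signature(config: RunConfig) -> RunResult:
    """Execute the configured workflow; returns output paths and results.

    Any stage error aborts the run with the stage name; files written so far
    are removed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = RunResult(out_dir=out_dir)
    stage = "startup"
    try:
        if config.scenario is not None:
            stage = "simulate"
            _simulate_inputs(config, out_dir / "inputs", result)

        stage = "load_reference"
        ref = load_reference(config.reference, config.annotation)
        null_props = origin_proportions(ref)

        stage = "load_counts"
        counts = CountMatrix.from_tsv(config.counts)
        sheet = read_sample_sheet(config.sample_sheet)
        missing = [s for s in counts.sample_ids if s not in sheet.index]
        if missing:
            raise ValueError(f"samples missing from sheet: {missing}")
        sheet = sheet.loc[counts.sample_ids]

        qc = {
            "n_reference": len(ref),
            "canonical_fraction": canonical_fraction(ref),
            "u1_fraction": u1_fraction(ref.sequences()),
        }
        if config.snorna is not None:
            stage = "snorna_screen"
            rep = snorna_overlap(ref, config.snorna)
            qc["snorna_overlap_fraction"] = rep.fraction_overlapping

        stage = "contrasts"
        if config.split_column and config.split_column in sheet.columns:
            cell_types = list(pd.unique(sheet[config.split_column]))
            subsets = {
                ct: sheet.index[sheet[config.split_column] == ct] for ct in cell_types
            }
        else:
            subsets = {"all": sheet.index}

        summary_lines = [
            f"pirsig {__version__} signature run (seed {config.seed})",
            f"reference: {qc['n_reference']} features, canonical fraction "
            f"{qc['canonical_fraction']:.3f}, 5'U fraction {qc['u1_fraction']:.3f}",
        ]
        if "snorna_overlap_fraction" in qc:
            summary_lines.append(
                f"snoRNA overlap fraction: {qc['snorna_overlap_fraction']:.4f}"
            )

        for ct, samples in subsets.items():
            sub_sheet = sheet.loc[samples]
            levels = sub_sheet[config.contrast_column].astype(str).value_counts()
            if len(levels) != 2 or (levels < 2).any():
                logger.warning(
                    "cell type %r: contrast %r lacks 2 levels with >=2 samples; skipped",
                    ct, config.contrast_column,
                )
                summary_lines.append(f"[{ct}] skipped (no valid contrast)")
                continue
            stage = f"de[{ct}]"
            covs = _usable_covariates(sub_sheet, config.covariates_for(ct))
            design = DesignSpec(
                contrast=config.contrast_column,
                covariates=covs,
                reference_level=config.reference_level,
            )
            sub_counts = counts.counts[samples]
            res = nb_wald(sub_counts, sub_sheet, design)
            call = call_deregulated(res, config.lfc_min, config.padj_max)
            result.de_results[ct] = res
            result.calls[ct] = call
            stage = f"write_de[{ct}]"
            de_path = out_dir / f"de_results_{ct}.tsv"
            write_de_results(res, call, de_path)
            result.files.append(de_path)

            sf = res.attrs["size_factors"]
            logm = log_transform(sub_counts, sf)
            normalized = sub_counts.div(sf, axis=1)

            stage = f"enrichment[{ct}]"
            enr_frames = []
            for which, ids in (("down", call.down), ("up", call.up)):
                if ids:
                    e = origin_enrichment(ids, ref, null_props).reset_index()
                    e.insert(0, "query_set", which)
                    enr_frames.append(e)
            enr = (
                pd.concat(enr_frames, ignore_index=True)
                if enr_frames
                else pd.DataFrame(
                    columns=["query_set", "origin_class", "k", "n", "p0",
                             "expected", "chi2", "p", "direction", "testable"]
                )
            )
            _write_tsv(
                enr.set_index("query_set"),
                out_dir / f"enrichment_{ct}.tsv",
                result,
                header_comment=f"cell_type={ct} null=genome-wide reference proportions",
            )

            stage = f"composition[{ct}]"
            comp = composition_bias(call.up, call.down, ref.ids, ref)
            _write_tsv(
                comp.to_frame(),
                out_dir / f"composition_{ct}.tsv",
                result,
                header_comment=f"cell_type={ct} base=C universe=all reference piRNAs",
            )

            stage = f"clustering[{ct}]"
            panel = top_de(res, config.top_de_n)
            clus = hcluster(logm, panel, sub_sheet, group_col=config.contrast_column)
            cdf = pd.DataFrame(
                {
                    "cluster": clus.labels,
                    "group": sub_sheet[config.contrast_column],
                }
            ).rename_axis("sample_id")
            _write_tsv(
                cdf,
                out_dir / f"clusters_{ct}.tsv",
                result,
                header_comment=(
                    f"cell_type={ct} panel=top{len(panel)} by padj "
                    f"distance=1-Pearson linkage=average ARI={clus.ari:.4f}"
                ),
            )

            top_ids, share = top_abundant_de(
                res, call, config.top_abundant_n, normalized=normalized
            )
            mean_share = float(share.mean()) if share is not None and top_ids else 0.0
            summary_lines.append(
                f"[{ct}] up={len(call.up)} down={len(call.down)} "
                f"cluster ARI={clus.ari:.3f} "
                f"top{config.top_abundant_n} abundant-DE count share={mean_share:.3f}"
            )

        stage = "memory"
        mem_rows = []
        ref_ct = config.memory_reference_cell_type
        if ref_ct in result.calls and result.calls[ref_ct].all_ids:
            for ct, call in result.calls.items():
                if ct == ref_ct or not call.all_ids:
                    continue
                rep = memory_fraction(
                    call,
                    result.calls[ref_ct],
                    direction_matched=config.direction_matched_memory,
                    stage=ct,
                )
                mem_rows.append(
                    {
                        "stage": ct,
                        "n_memory": rep.n_memory,
                        "n_total_deregulated": rep.n_total_deregulated,
                        "fraction": rep.fraction,
                    }
                )
                summary_lines.append(
                    f"memory[{ct} vs {ref_ct}]: {rep.n_memory}/{rep.n_total_deregulated}"
                    f" = {rep.fraction:.3f}"
                )
        mem = pd.DataFrame(
            mem_rows, columns=["stage", "n_memory", "n_total_deregulated", "fraction"]
        ).set_index("stage")
        _write_tsv(
            mem,
            out_dir / "memory.tsv",
            result,
            header_comment=(
                f"reference stage={ref_ct} "
                f"direction_matched={config.direction_matched_memory}"
            ),
        )

        stage = "overlap"
        ov_rows = []
        cts = sorted(result.calls)
        for i, a in enumerate(cts):
            for b in cts[i + 1:]:
                rep = direction_overlap(result.calls[a], result.calls[b])
                ov_rows.append(
                    {
                        "cohort_a": a,
                        "cohort_b": b,
                        "up_shared": rep.n_up_shared,
                        "down_shared": rep.n_down_shared,
                        "shared_deregulated": rep.n_shared_deregulated,
                        "up_a": rep.n_up_a,
                        "up_b": rep.n_up_b,
                        "down_a": rep.n_down_a,
                        "down_b": rep.n_down_b,
                    }
                )
        ov = pd.DataFrame(
            ov_rows,
            columns=["cohort_a", "cohort_b", "up_shared", "down_shared",
                     "shared_deregulated", "up_a", "up_b", "down_a", "down_b"],
        ).set_index("cohort_a")
        _write_tsv(ov, out_dir / "overlap.tsv", result)

        stage = "manifest"
        manifest = {
            "tool": "pirsig",
            "version": __version__,
            "config": config_as_dict(config),
            "qc": qc,
            "outputs": sorted(str(p.relative_to(out_dir)) for p in result.files),
        }
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        result.files.append(mpath)
        spath = out_dir / "summary.txt"
        spath.write_text("\n".join(summary_lines) + "\n")
        result.files.append(spath)
        return result
    except Exception as exc:
        for p in result.files:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
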