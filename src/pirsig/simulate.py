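"""Synthetic data with the statistical structure the analysis assumes.

Generates piRNA references (canonical 24-32 nt plus shorter piRNA-like
species, 5'U bias, element-of-origin mixtures with a SINE-enriched override
for planted down-regulated features, elevated cytosine probability at
positions 2-9 for planted up-regulated features), NB-distributed count
matrices with planted group effects and library-size variation, sample
sheets, optional error-bearing FASTQ reads, and ground-truth tables for
parameter-recovery testing.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` handed to sub-steps in fixed order, so identical
parameters yield byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .quantify import CountMatrix, ReadSet
from .reference import PiRNARecord, ReferenceSet

_BASES = np.array(list("ACGU"))

SCENARIOS = ("null", "pd_neuron", "differentiation")


def _default_origin_probs() -> dict[str, float]:
    return {"SINE": 0.2, "LINE": 0.15, "LTR": 0.1, "GENIC": 0.25, "OTHER": 0.3, "UNKNOWN": 0.0}


def _sine_enriched_origin_probs() -> dict[str, float]:
    # override for planted down-regulated features: SINE-heavy, LINE above null
    return {"SINE": 0.5, "LINE": 0.2, "LTR": 0.05, "GENIC": 0.1, "OTHER": 0.15, "UNKNOWN": 0.0}


def _default_base_probs() -> dict[str, float]:
    return {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study.

    Counts follow NB(mean, dispersion alpha) with per-feature baseline means
    2^Normal(baseline_log2_mean, baseline_log2_sd), a planted log2 fold
    change of +/- lfc_abs on a de_frac share of features, and per-sample
    library-size multipliers log-uniform in [0.5, 2].
    """

    n_features: int = 2000
    origin_probs: Mapping[str, float] = field(default_factory=_default_origin_probs)
    down_origin_probs: Mapping[str, float] | None = None
    canonical_frac: float = 0.8
    u1_prob: float = 0.8
    c_bias_positions: tuple[int, ...] = tuple(range(2, 10))
    c_bias_prob: float = 0.6
    background_base_probs: Mapping[str, float] = field(default_factory=_default_base_probs)
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CTRL": 8, "PD": 8}
    )
    baseline_log2_mean: float = 6.64  # ~100 counts
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.1
    de_frac: float = 0.0
    lfc_abs: float = 1.5
    frac_de_down: float = 0.6
    sex_effect_log2: float = 0.0
    memory_share: float = 0.0
    cell_type: str = "neuron"
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (
            ("origin_probs", self.origin_probs),
            ("background_base_probs", self.background_base_probs),
        ):
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability simplex")
        if self.down_origin_probs is not None:
            vals = np.array(list(self.down_origin_probs.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError("down_origin_probs must be a probability simplex")
        for p in (self.canonical_frac, self.u1_prob, self.c_bias_prob, self.de_frac,
                  self.frac_de_down, self.memory_share):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("need at least 2 samples per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def scenario(name: str, seed: int = 0) -> SimParams:
    """Preset parameters for the three study frames.

    ``null``: no planted effects (calibration checks). ``pd_neuron``: a
    disease-vs-control contrast in one cell type with planted effects, a
    SINE-enriched down set and cytosine bias on the up set.
    ``differentiation``: two stages whose planted deregulated sets share a
    small (8%) "memory" fraction.
    """
    if name == "null":
        return SimParams(n_features=2000, de_frac=0.0, seed=seed)
    if name == "pd_neuron":
        return SimParams(
            n_features=5000,
            de_frac=0.04,
            lfc_abs=1.5,
            frac_de_down=0.6,
            down_origin_probs=_sine_enriched_origin_probs(),
            sex_effect_log2=0.25,
            cell_type="neuron",
            seed=seed,
        )
    if name == "differentiation":
        return SimParams(
            n_features=5000,
            de_frac=0.04,
            lfc_abs=1.5,
            frac_de_down=0.6,
            down_origin_probs=_sine_enriched_origin_probs(),
            memory_share=0.08,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


def _plant_directions(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Assign up/down/null per feature according to de_frac and frac_de_down."""
    n = params.n_features
    n_de = int(round(params.de_frac * n))
    n_down = int(round(params.frac_de_down * n_de))
    directions = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    directions[perm[:n_down]] = "down"
    directions[perm[n_down:n_de]] = "up"
    return directions


def _draw_sequence(
    length: int,
    direction: str,
    params: SimParams,
    rng: np.random.Generator,
) -> str:
    bg = np.array([params.background_base_probs[b] for b in "ACGU"])
    chars = list(_BASES[rng.choice(4, size=length, p=bg)])
    # 5'U bias
    if rng.random() < params.u1_prob:
        chars[0] = "U"
    else:
        others = [b for b in "ACG"]
        w = np.array([params.background_base_probs[b] for b in others])
        w = w / w.sum() if w.sum() > 0 else np.full(3, 1 / 3)
        chars[0] = others[rng.choice(3, p=w)]
    # planted cytosine bias on up-regulated features
    if direction == "up":
        for pos in params.c_bias_positions:
            if pos <= length:
                if rng.random() < params.c_bias_prob:
                    chars[pos - 1] = "C"
                else:
                    others = [b for b in "AGU"]
                    w = np.array([params.background_base_probs[b] for b in others])
                    w = w / w.sum() if w.sum() > 0 else np.full(3, 1 / 3)
                    chars[pos - 1] = others[rng.choice(3, p=w)]
    return "".join(chars)


def simulate_reference(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Generate a reference and the partial truth table (direction, origin, bias).

    Planted "down" features draw their origin class from the SINE-enriched
    override (when set); planted "up" features carry the positional cytosine
    bias. Lengths are uniform on 24-32 nt for the canonical share and on
    18-23 nt (piRNA-like) otherwise.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    directions = _plant_directions(params, rng)

    classes = list(params.origin_probs)
    p_null = np.array([params.origin_probs[c] for c in classes])
    if params.down_origin_probs is not None:
        down_classes = list(params.down_origin_probs)
        p_down = np.array([params.down_origin_probs[c] for c in down_classes])
    else:
        down_classes, p_down = classes, p_null

    records = []
    rows = []
    for i in range(params.n_features):
        fid = f"pir{i:05d}"
        direction = directions[i]
        if rng.random() < params.canonical_frac:
            length = int(rng.integers(24, 33))
        else:
            length = int(rng.integers(18, 24))
        seq = _draw_sequence(length, direction, params, rng)
        if direction == "down":
            origin = down_classes[rng.choice(len(down_classes), p=p_down)]
        else:
            origin = classes[rng.choice(len(classes), p=p_null)]
        records.append(PiRNARecord(id=fid, sequence=seq, origin_class=origin))
        rows.append(
            {
                "feature_id": fid,
                "direction": direction,
                "origin_class": origin,
                "c_bias": direction == "up",
            }
        )
    truth = pd.DataFrame(rows).set_index("feature_id")
    return ReferenceSet(records), truth


def _make_sheet(
    params: SimParams, rng: np.random.Generator, prefix: str = "", cell_type: str | None = None
) -> pd.DataFrame:
    rows = {}
    patient = 0
    for grp, n in params.n_per_group.items():
        for j in range(n):
            patient += 1
            sid = f"{prefix}{grp}{j + 1:02d}"
            rows[sid] = {
                "group": grp,
                "cell_type": cell_type or params.cell_type,
                "sex": "F" if j % 2 == 0 else "M",
                "passage": int(rng.integers(5, 30)),
                "patient_id": f"pt{patient:03d}",
            }
    sheet = pd.DataFrame.from_dict(rows, orient="index")
    sheet.index.name = "sample_id"
    return sheet


def simulate_counts(
    ref: ReferenceSet,
    params: SimParams,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "",
    cell_type: str | None = None,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw NB counts with planted group effects; returns (counts, sheet, truth).

    Feature i has baseline mean 2^N(mu, sd); the second group's mean is
    multiplied by 2^(true log2FC); a sex covariate may shift log-means; each
    sample carries a log-uniform [0.5, 2] size multiplier. The returned truth
    table adds the true log2FC to the per-feature plant.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    truth = truth.loc[ref.ids].copy()
    sheet = _make_sheet(params, rng, prefix=sample_prefix, cell_type=cell_type)

    n_feat = len(ref)
    groups = list(params.n_per_group)
    alt_group = groups[1]
    b = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n_feat)
    lfc = np.where(
        truth["direction"] == "up",
        params.lfc_abs,
        np.where(truth["direction"] == "down", -params.lfc_abs, 0.0),
    )
    size_mult = 2.0 ** rng.uniform(-1.0, 1.0, size=len(sheet))
    is_alt = (sheet["group"] == alt_group).to_numpy(dtype=float)
    is_f = (sheet["sex"] == "F").to_numpy(dtype=float)

    log2_mean = (
        b[:, None]
        + lfc[:, None] * is_alt[None, :]
        + params.sex_effect_log2 * is_f[None, :]
        + np.log2(size_mult)[None, :]
    )
    mu = 2.0 ** log2_mean
    if params.dispersion > 1e-8:
        r = 1.0 / params.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)
    cm = CountMatrix(pd.DataFrame(counts, index=ref.ids, columns=sheet.index))
    truth["true_log2fc"] = lfc
    return cm, sheet, truth


@dataclass
class SimDataset:
    """One simulated contrast: reference, counts, sample sheet, ground truth."""

    ref: ReferenceSet
    counts: CountMatrix
    sheet: pd.DataFrame
    truth: pd.DataFrame


def simulate_dataset(params: SimParams) -> SimDataset:
    """Reference plus one count matrix, all from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    ref, truth = simulate_reference(params, rng)
    counts, sheet, truth = simulate_counts(ref, params, truth, rng)
    return SimDataset(ref=ref, counts=counts, sheet=sheet, truth=truth)


@dataclass
class MemoryPair:
    """Two differentiation stages sharing a planted fraction of DE features."""

    ref: ReferenceSet
    stages: dict[str, SimDataset]
    planted_share: float


def simulate_memory_pair(params: SimParams) -> MemoryPair:
    """Fibroblast and neuron stage datasets with overlapping planted DE sets.

    The neuron stage's planted set drives the sequence-level biases; the
    fibroblast stage's planted set is the same size and shares
    round(memory_share * n_de) features (keeping their direction), emulating
    an epigenetic-memory fraction.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ref, truth_neuron = simulate_reference(params, rng)

    ids = np.array(ref.ids)
    neuron_de = truth_neuron.index[truth_neuron["direction"] != "null"]
    n_de = len(neuron_de)
    n_shared = int(round(params.memory_share * n_de))
    shared = rng.choice(neuron_de.to_numpy(), size=n_shared, replace=False)

    null_pool = truth_neuron.index[truth_neuron["direction"] == "null"].to_numpy()
    fresh = rng.choice(null_pool, size=n_de - n_shared, replace=False)
    truth_fibro = truth_neuron.copy()
    truth_fibro["direction"] = "null"
    truth_fibro.loc[shared, "direction"] = truth_neuron.loc[shared, "direction"]
    n_down_fresh = int(round(params.frac_de_down * len(fresh)))
    truth_fibro.loc[fresh[:n_down_fresh], "direction"] = "down"
    truth_fibro.loc[fresh[n_down_fresh:], "direction"] = "up"
    truth_fibro["c_bias"] = False

    counts_f, sheet_f, truth_f = simulate_counts(
        ref, params, truth_fibro, rng, sample_prefix="F_", cell_type="fibroblast"
    )
    counts_n, sheet_n, truth_n = simulate_counts(
        ref, params, truth_neuron, rng, sample_prefix="N_", cell_type="neuron"
    )
    return MemoryPair(
        ref=ref,
        stages={
            "fibroblast": SimDataset(ref, counts_f, sheet_f, truth_f),
            "neuron": SimDataset(ref, counts_n, sheet_n, truth_n),
        },
        planted_share=n_shared / n_de if n_de else 0.0,
    )


def simulate_reads(
    ref: ReferenceSet,
    counts_column: Mapping[str, int] | pd.Series,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "S1",
) -> ReadSet:
    """Emit each reference sequence count-many times with per-base errors.

    Errors substitute a base with one of the other three uniformly. Returns
    reads in the DNA alphabet (U->T), as a sequencer would deliver them.
    """
    if not (0.0 <= error_rate <= 0.05):
        raise ValueError("error_rate must lie in [0, 0.05]")
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(counts_column, pd.Series):
        counts_column = counts_column.to_dict()
    reads: list[str] = []
    for rid in ref.ids:
        c = int(counts_column.get(rid, 0))
        if c < 0:
            raise ValueError(f"negative count for {rid}")
        seq = ref[rid].sequence
        for _ in range(c):
            chars = list(seq)
            if error_rate > 0:
                errs = rng.random(len(chars)) < error_rate
                for k in np.flatnonzero(errs):
                    alts = [b for b in "ACGU" if b != chars[k]]
                    chars[k] = alts[rng.integers(3)]
            reads.append("".join(chars).replace("U", "T"))
    return ReadSet(sample_id=sample_id, reads=reads)


def write_fastq(reads: ReadSet, path: str | Path, quality_char: str = "I") -> None:
    """Write reads as plain FASTQ with constant quality strings."""
    with open(path, "wt") as fh:
        for i, r in enumerate(reads.reads):
            fh.write(f"@{reads.sample_id}_read{i:07d}\n{r}\n+\n{quality_char * len(r)}\n")


def write_annotation(ref: ReferenceSet, path: str | Path) -> None:
    """Write the id -> origin_class annotation TSV for a reference."""
    with open(path, "wt") as fh:
        fh.write("id\torigin_class\n")
        for rec in ref:
            fh.write(f"{rec.id}\t{rec.origin_class}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.rename_axis("feature_id").to_csv(path, sep="\t", lineterminator="\n")
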