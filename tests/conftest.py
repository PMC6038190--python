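import numpy as np
import pytest

from pirsig.reference import PiRNARecord, ReferenceSet


@pytest.fixture
def tiny_ref() -> ReferenceSet:
    """Four hand-built reference records with known origins and lengths."""
    return ReferenceSet(
        [
            PiRNARecord("p1", "UACGUACGUACGUACGUACGUACG", "SINE"),  # 24 nt canonical
            PiRNARecord("p2", "ACGUACGUACGUACGUACGUACGUACGUACGU", "SINE"),  # 32 nt
            PiRNARecord("p3", "UUGGCCAAUUGGCCAAUUGG", "LINE"),  # 20 nt piRNA-like
            PiRNARecord("p4", "CCCCAAAAGGGGUUUUCCCCAAAA", "SINE"),  # 24 nt
        ]
    )


@pytest.fixture
def ref_files(tmp_path):
    """A small FASTA (DNA alphabet) + annotation TSV on disk."""
    fasta = tmp_path / "ref.fasta"
    fasta.write_text(
        ">p1\nTACGTACGTACGTACGTACGTACG\n"
        ">p2\nACGTACGTACGTACGTACGT\n"
        ">p3\nGGGGCCCCAAAATTTTGGGGCCCCAAAATTTT\n"
    )
    ann = tmp_path / "ann.tsv"
    ann.write_text("id\torigin_class\np1\tSINE\np3\tLINE\n")
    return fasta, ann


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_call_sets(rng, n_ids=30):
    """Helper: two random disjoint-up/down call pairs over a shared id pool."""
    from pirsig.de import DECall

    ids = [f"f{i}" for i in range(n_ids)]
    out = []
    for _ in range(2):
        picks = rng.permutation(ids)
        k1, k2 = rng.integers(0, n_ids // 2, size=2)
        out.append(DECall(up=frozenset(picks[:k1]), down=frozenset(picks[k1:k1 + k2])))
    return out
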