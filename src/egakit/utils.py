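"""Small shared helpers: sequence utilities, RNG plumbing, expression summaries."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: integer codes used throughout for sequence arrays; 4 = ambiguous (N)
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_TO_BASE = "ACGTN"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0..T=3, anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


def child_seed(seed: int, *labels: str | int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a base seed and labels.

    A documented alternative to passing generators around: every stage of the
    pipeline draws from its own stream so inserting a stage never perturbs the
    randomness of the others.
    """
    ss = np.random.SeedSequence([seed] + [_label_int(l) for l in labels])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _label_int(label: str | int) -> int:
    if isinstance(label, int):
        return label
    return int.from_bytes(label.encode("utf8"), "little") % (2**31 - 1)


def mean_reads_per_detected_sample(values) -> float:
    """Mean normalized read count over the samples in which a signal was detected.

    The convention used for sparse promoter-level tag data: a feature seen in
    only a handful of a large sample panel is summarized as (total reads) /
    (number of samples with at least one read), not as a panel-wide mean.

    Parameters
    ----------
    values : array-like of per-sample normalized read counts.

    Raises
    ------
    ValueError if no sample has a positive count.
    """
    v = np.asarray(values, dtype=float)
    detected = v > 0
    if not detected.any():
        raise ValueError("no sample with detected expression")
    return float(v[detected].sum() / detected.sum())


def jaccard(a: set, b: set) -> float:
    """Jaccard similarity of two sets; 1.0 when both are empty."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
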