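"""Five co-elution features per candidate protein pair.

Members of a stable complex co-elute, so their elution profiles agree; the
classifier's evidence for a pair is five complementary similarity scores:

* ``pearson`` — product-moment correlation of the normalized profiles;
* ``jaccard`` — overlap of the detection supports (fractions with counts);
* ``apex`` — 1 iff the two profiles peak in the same fraction;
* ``mi`` — mutual information (bits) of the binned profiles;
* ``bayes`` — correlation of Dirichlet-smoothed count proportions, robust
  at low counts (additive pseudocount alpha on every fraction).

Profiles from the different separation experiments are normalized per
experiment and concatenated before scoring, so a pair must track across
techniques — two complexes that co-elute on every size-based column are
still resolved by their independent IEX positions. Pairs whose Pearson
similarity is not strictly above the prefilter (default 0.5) are discarded.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .profiles import ProfileMatrix, concatenate_profiles

FEATURE_COLUMNS = ["pearson", "jaccard", "apex", "mi", "bayes"]


def pearson_feature(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r of two profiles; NaN when either has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UsageError("profiles differ in length")
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def jaccard_feature(x: Sequence[float], y: Sequence[float]) -> float:
    """Jaccard index of the detection supports (count > 0); 0 if both empty."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise UsageError("profiles differ in length")
    a = x > 0
    b = y > 0
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)


def apex_feature(x: Sequence[float], y: Sequence[float]) -> int:
    """1 iff the argmax fractions coincide (ties resolve to the earliest)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return int(np.argmax(x) == np.argmax(y))


def mutual_information_feature(
    x: Sequence[float], y: Sequence[float], n_bins: int = 5
) -> float:
    """MI (bits) between equal-width binnings of the two profiles.

    Each profile is discretized into `n_bins` equal-width bins over
    [0, max(profile)]; a constant profile falls into a single bin and
    contributes zero information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UsageError("profiles differ in length")
    if x.size < n_bins:
        raise UsageError(f"need at least n_bins={n_bins} fractions, got {x.size}")
    bx = _discretize(x, n_bins)
    by = _discretize(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    for i, j in zip(bx, by):
        joint[i, j] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            p = joint[i, j]
            if p > 0:
                mi += p * math.log2(p / (px[i] * py[j]))
    return max(mi, 0.0)


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    mx = x.max()
    if mx <= 0:
        return np.zeros(x.size, dtype=int)
    edges = np.linspace(0.0, mx, n_bins + 1)
    return np.clip(np.digitize(x, edges[1:-1], right=False), 0, n_bins - 1)


def bayes_correlation_feature(
    x: Sequence[float], y: Sequence[float], alpha: float = 1.0
) -> float:
    """Shrinkage correlation for count vectors.

    Adds a Dirichlet pseudocount `alpha` to every fraction, converts each
    vector to proportions of its total, and returns the Pearson correlation
    of the proportion vectors. NaN when a smoothed vector is constant
    (e.g. both inputs all-zero).
    """
    if alpha <= 0:
        raise UsageError("alpha must be > 0")
    x = np.asarray(x, dtype=float) + alpha
    y = np.asarray(y, dtype=float) + alpha
    if x.size != y.size:
        raise UsageError("profiles differ in length")
    return pearson_feature(x / x.sum(), y / y.sum())


def build_feature_table(
    matrices: Sequence[ProfileMatrix],
    retained_proteins: Iterable[str],
    prefilter: float = 0.5,
    n_bins: int = 5,
    alpha: float = 1.0,
    window: int = 3,
) -> pd.DataFrame:
    """Score all candidate pairs and apply the similarity prefilter.

    Candidates are unordered pairs of retained proteins detected together in
    at least one experiment and with non-degenerate concatenated profiles.
    Pairs whose Pearson similarity is <= `prefilter` are dropped (the cutoff
    is strict). Output columns: protein_a, protein_b, the five features, and
    n_experiments (co-detection count), sorted by pair id.
    """
    if not matrices:
        raise UsageError("no profile matrices supplied")
    universe = set()
    for m in matrices:
        universe.update(m.proteins)
    proteins = sorted(set(retained_proteins) & universe)
    if not proteins:
        raise UsageError("no retained proteins present in the matrices")

    raw, norm, present = concatenate_profiles(matrices, proteins, window=window)
    n = len(proteins)
    stds = norm.std(axis=1)
    valid = stds > 0

    # Pearson prefilter for all pairs at once on the concatenated profiles
    centered = norm - norm.mean(axis=1, keepdims=True)
    safe_std = np.where(valid, stds, 1.0)
    corr = (centered @ centered.T) / (
        norm.shape[1] * np.outer(safe_std, safe_std)
    )  # corr[i,j] valid only where both rows valid

    shared = present.astype(int) @ present.astype(int).T  # co-detection counts

    rows = []
    for i in range(n):
        if not valid[i]:
            continue
        for j in range(i + 1, n):
            if not valid[j] or shared[i, j] < 1:
                continue
            r = corr[i, j]
            if not (r > prefilter):
                continue
            rows.append(
                (
                    proteins[i],
                    proteins[j],
                    float(r),
                    jaccard_feature(raw[i], raw[j]),
                    apex_feature(norm[i], norm[j]),
                    mutual_information_feature(norm[i], norm[j], n_bins=n_bins),
                    bayes_correlation_feature(raw[i], raw[j], alpha=alpha),
                    int(shared[i, j]),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["protein_a", "protein_b", *FEATURE_COLUMNS, "n_experiments"],
    )
    table = table.dropna(subset=FEATURE_COLUMNS)
    return table.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
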