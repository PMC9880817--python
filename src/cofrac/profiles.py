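"""Elution-profile matrices: reading, validation, filtering, normalization.

A co-fractionation experiment yields, per protein, a vector of spectral
counts across ordered fractions (the elution profile). This module owns the
in-memory container for one experiment's profile matrix, the PSM-based
identification filter, the normalization/smoothing used before feature
computation, and the replicate-reproducibility statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

TECHNIQUES = ("SEC", "IEX", "SDGC")

_COLUMN_RE = re.compile(r"^(?P<exp>[A-Za-z]+\d*)_F(?P<idx>\d+)$")


@dataclass
class ProfileMatrix:
    """Protein x fraction spectral-count table for one separation experiment."""

    experiment_id: str
    technique: str
    proteins: list[str]
    counts: np.ndarray  # shape (n_proteins, n_fractions), non-negative ints
    fraction_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.proteins):
            raise FormatError("counts shape does not match protein list")
        if not self.fraction_labels:
            self.fraction_labels = [
                f"{self.experiment_id}_F{i + 1}" for i in range(self.counts.shape[1])
            ]
        if len(self.fraction_labels) != self.counts.shape[1]:
            raise FormatError("fraction labels do not match matrix width")
        if len(set(self.proteins)) != len(self.proteins):
            dupes = {p for p in self.proteins if self.proteins.count(p) > 1}
            raise FormatError(f"duplicate protein ids: {sorted(dupes)}")
        if np.any(self.counts < 0):
            raise FormatError("negative spectral counts")
        if self.technique not in TECHNIQUES:
            raise FormatError(f"unknown technique {self.technique!r}")

    @property
    def n_fractions(self) -> int:
        return self.counts.shape[1]

    def row(self, protein: str) -> np.ndarray:
        return self.counts[self.proteins.index(protein)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.fraction_labels)
        df.insert(0, "protein_id", self.proteins)
        return df


def technique_of(experiment_id: str) -> str:
    """Leading alphabetic part of an experiment id, e.g. SEC2 -> SEC."""
    name = experiment_id.rstrip("0123456789")
    if name not in TECHNIQUES:
        raise FormatError(
            f"cannot infer technique from experiment id {experiment_id!r}"
        )
    return name


def read_fraction_table(path) -> ProfileMatrix:
    """Read a tab-delimited fraction table.

    First column: protein id; remaining columns named ``<experiment>_F<i>``
    in elution order. Counts must be non-negative integers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need an id column plus >=1 fraction column")
    fraction_cols = list(df.columns[1:])
    exp_ids = set()
    for col in fraction_cols:
        m = _COLUMN_RE.match(col)
        if not m:
            raise FormatError(f"{path}: malformed fraction column {col!r}")
        exp_ids.add(m.group("exp"))
    if len(exp_ids) != 1:
        raise FormatError(f"{path}: mixed experiment ids in header: {sorted(exp_ids)}")
    experiment_id = exp_ids.pop()
    proteins = df.iloc[:, 0].astype(str).tolist()
    dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate protein ids {sorted(set(dupes))}")
    values = df[fraction_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        rounded = np.asarray(values, dtype=float)
        if np.any(rounded != np.floor(rounded)):
            bad = np.argwhere(rounded != np.floor(rounded))[0]
            raise FormatError(
                f"{path}: non-integer count at row {proteins[bad[0]]}, "
                f"column {fraction_cols[bad[1]]}"
            )
        values = rounded.astype(np.int64)
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative count at row {proteins[bad[0]]}, "
            f"column {fraction_cols[bad[1]]}"
        )
    return ProfileMatrix(
        experiment_id=experiment_id,
        technique=technique_of(experiment_id),
        proteins=proteins,
        counts=values,
        fraction_labels=fraction_cols,
    )


def write_fraction_table(matrix: ProfileMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def filter_min_psm(
    matrices: Sequence[ProfileMatrix], min_psm: int = 2
) -> tuple[set[str], dict[str, str]]:
    """Identification filter: keep proteins with >= `min_psm` spectral counts
    in at least one single fraction of at least one experiment.

    Returns the retained protein set and a per-protein reason log.
    """
    if not matrices:
        raise UsageError("filter_min_psm needs at least one profile matrix")
    if min_psm < 1:
        raise UsageError("min_psm must be >= 1")
    best: dict[str, int] = {}
    for m in matrices:
        if m.counts.size == 0:
            continue
        row_max = m.counts.max(axis=1)
        for protein, mx in zip(m.proteins, row_max):
            best[protein] = max(best.get(protein, 0), int(mx))
    retained = {p for p, mx in best.items() if mx >= min_psm}
    reasons = {
        p: (
            f"retained: max single-fraction count {mx} >= {min_psm}"
            if mx >= min_psm
            else f"removed: max single-fraction count {mx} < {min_psm}"
        )
        for p, mx in best.items()
    }
    return retained, reasons


def normalize_and_smooth(profile: Sequence[float], window: int = 3) -> np.ndarray:
    """Max-normalize a count vector, then apply a centered moving average.

    The moving average truncates at the edges (averages over the fractions
    actually available). All-zero vectors pass through unchanged; output is
    in [0, 1].
    """
    if window < 1 or window % 2 == 0:
        raise UsageError(f"window must be odd and >=1, got {window}")
    x = np.asarray(profile, dtype=float)
    mx = x.max() if x.size else 0.0
    if mx > 0:
        x = x / mx
    if window == 1 or x.size == 0:
        return x
    # centered moving average with edge truncation via cumulative sums
    half = window // 2
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def replicate_correlation(
    a: ProfileMatrix, b: ProfileMatrix
) -> tuple[pd.Series, float]:
    """Per-protein Pearson r between two replicate experiments.

    Requires equal fraction counts. Proteins with zero variance in either
    replicate are reported as NaN (undefined), never as 0. Returns the
    per-protein series (indexed by protein id) and the median of the
    defined correlations.
    """
    if a.n_fractions != b.n_fractions:
        raise UsageError(
            f"replicates have different fraction counts: "
            f"{a.n_fractions} vs {b.n_fractions}"
        )
    shared = sorted(set(a.proteins) & set(b.proteins))
    if not shared:
        raise UsageError("no shared proteins between replicates")
    idx_a = {p: i for i, p in enumerate(a.proteins)}
    idx_b = {p: i for i, p in enumerate(b.proteins)}
    out = {}
    for p in shared:
        x = a.counts[idx_a[p]].astype(float)
        y = b.counts[idx_b[p]].astype(float)
        if x.std() == 0 or y.std() == 0:
            out[p] = np.nan
        else:
            out[p] = float(np.corrcoef(x, y)[0, 1])
    series = pd.Series(out, name="pearson_r")
    return series, float(series.dropna().median())


def detected_proteins(matrix: ProfileMatrix) -> set[str]:
    """Proteins with any nonzero count in the experiment."""
    nz = matrix.counts.sum(axis=1) > 0
    return {p for p, d in zip(matrix.proteins, nz) if d}


def concatenate_profiles(
    matrices: Iterable[ProfileMatrix], proteins: Sequence[str], window: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack experiments column-wise for a common protein list.

    Returns ``(raw, normalized, present)`` where `raw` and `normalized` are
    (n_proteins, total_fractions) arrays (zeros where a protein is absent
    from an experiment) and `present` is a boolean (n_proteins, n_experiments)
    detection indicator (any nonzero count).
    """
    matrices = list(matrices)
    n = len(proteins)
    raw_blocks, norm_blocks, present = [], [], np.zeros((n, len(matrices)), bool)
    for k, m in enumerate(matrices):
        idx = {p: i for i, p in enumerate(m.proteins)}
        raw = np.zeros((n, m.n_fractions))
        norm = np.zeros((n, m.n_fractions))
        for j, p in enumerate(proteins):
            i = idx.get(p)
            if i is None:
                continue
            raw[j] = m.counts[i]
            norm[j] = normalize_and_smooth(m.counts[i], window=window)
            present[j, k] = m.counts[i].sum() > 0
        raw_blocks.append(raw)
        norm_blocks.append(norm)
    return np.hstack(raw_blocks), np.hstack(norm_blocks), present
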