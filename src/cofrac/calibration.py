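"""SEC molecular-mass calibration, apparent mass, and oligomer-state calls.

Size-exclusion chromatography separates native species by size: within the
column's working range, log10(molecular mass) is linear in elution fraction
index. A small set of protein standards of known mass is run on the same
column; an ordinary least-squares fit of log10(mass) on peak fraction yields
the calibration line. The apparent mass (Mapp) of any protein is then read
off the line at the fraction where its elution profile peaks, and the ratio
Rapp = Mapp / Mmono (Mmono = sequence-predicted monomer mass) summarizes its
oligomerization state:

    Rapp >= 2    -> complexed  (elutes at least twice its monomer mass)
    Rapp <= 0.5  -> degraded   (elutes well below its monomer mass;
                                dropped before pair scoring)
    otherwise    -> monomeric
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, UndefinedMassError, UsageError

log = logging.getLogger(__name__)

COMPLEXED = "complexed"
MONOMERIC = "monomeric"
DEGRADED = "degraded"

#: (name, mass in kDa) of the standards run on the SEC column.
DEFAULT_STANDARDS = (
    ("thyroglobulin", 669.0),
    ("BSA", 66.5),
    ("albumin_egg", 44.3),
    ("myoglobin", 17.0),
)

RAPP_COMPLEXED_MIN = 2.0
RAPP_DEGRADED_MAX = 0.5


@dataclass(frozen=True)
class CalibrationModel:
    """Log-linear SEC calibration: log10(mass_kDa) = slope * fraction + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int

    def mass_at(self, fraction: float) -> float:
        """Apparent mass (kDa) at a (possibly fractional) fraction index."""
        return float(10.0 ** (self.slope * fraction + self.intercept))

    def fraction_at(self, mass_kda: float) -> float:
        """Inverse of the line: fraction index at which `mass_kda` elutes."""
        return float((np.log10(mass_kda) - self.intercept) / self.slope)


@dataclass(frozen=True)
class RappRecord:
    protein_id: str
    m_app: float
    m_mono: float
    r_app: float
    state: str


def fit_calibration(standards: Iterable[tuple[float, float]]) -> CalibrationModel:
    """OLS fit of log10(mass) on peak fraction.

    Parameters
    ----------
    standards
        Iterable of ``(mass_kDa, peak_fraction)`` pairs; at least two
        distinct fractions are required.
    """
    pairs = list(standards)
    masses = np.asarray([m for m, _ in pairs], dtype=float)
    fractions = np.asarray([f for _, f in pairs], dtype=float)
    if len(pairs) < 2 or len(np.unique(fractions)) < 2:
        raise CalibrationError(
            f"calibration needs >=2 standards at distinct fractions, got {len(pairs)}"
        )
    if np.any(masses <= 0):
        raise CalibrationError("standard masses must be positive")
    res = stats.linregress(fractions, np.log10(masses))
    if res.slope == 0:
        raise CalibrationError("degenerate calibration: zero slope")
    r2 = 1.0 if len(pairs) == 2 else float(res.rvalue**2)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_standards=len(pairs),
    )


def true_calibration(
    n_fractions: int, mass_high_kda: float = 3000.0, mass_low_kda: float = 3.0
) -> CalibrationModel:
    """Exact calibration line spanning a column's working mass range.

    Fraction 1 elutes `mass_high_kda`, the last fraction `mass_low_kda`.
    Used by the simulator to place peaks; downstream code always refits from
    standards instead of using this line directly.
    """
    if n_fractions < 2:
        raise CalibrationError("need at least 2 fractions")
    slope = (np.log10(mass_low_kda) - np.log10(mass_high_kda)) / (n_fractions - 1)
    intercept = np.log10(mass_high_kda) - slope
    return CalibrationModel(float(slope), float(intercept), 1.0, 0)


def apparent_mass(profile: Sequence[float], model: CalibrationModel) -> float:
    """Mapp from the apex (argmax) fraction of a profile; ties -> earliest fraction."""
    values = np.asarray(profile, dtype=float)
    if not np.any(values > 0):
        raise UndefinedMassError("all-zero profile has no apex")
    apex_fraction = int(np.argmax(values)) + 1  # fractions are 1-based
    return model.mass_at(apex_fraction)


def classify_state(m_app: float, m_mono: float, protein_id: str = "") -> RappRecord:
    """Deterministic oligomer-state call from Rapp = Mapp / Mmono."""
    if m_mono <= 0:
        raise UsageError(f"monomer mass must be positive, got {m_mono}")
    r_app = m_app / m_mono
    if r_app >= RAPP_COMPLEXED_MIN:
        state = COMPLEXED
    elif r_app <= RAPP_DEGRADED_MAX:
        state = DEGRADED
    else:
        state = MONOMERIC
    return RappRecord(protein_id, float(m_app), float(m_mono), float(r_app), state)


def rapp_table(matrix, model, monomer_masses, window=3):
    """Per-protein Rapp records for one SEC experiment.

    Profiles are max-normalized and smoothed before apex picking. Proteins
    with an all-zero profile or no monomer-mass entry are omitted (logged).

    Parameters
    ----------
    matrix : profiles.ProfileMatrix
    model : CalibrationModel
    monomer_masses : Mapping[str, float]
    window : odd moving-average width used for smoothing.
    """
    from .profiles import normalize_and_smooth

    records: dict[str, RappRecord] = {}
    for i, protein in enumerate(matrix.proteins):
        mono = monomer_masses.get(protein)
        if mono is None:
            log.warning("no monomer mass for %s; skipped", protein)
            continue
        smooth = normalize_and_smooth(matrix.counts[i], window=window)
        try:
            m_app = apparent_mass(smooth, model)
        except UndefinedMassError:
            continue
        records[protein] = classify_state(m_app, mono, protein)
    return records


def combine_states(tables: Sequence[Mapping[str, RappRecord]]) -> dict[str, str]:
    """Merge per-SEC-experiment calls into one state per protein.

    A degraded call in any SEC experiment dominates (the protein is dropped
    from pair scoring); otherwise a complexed call in any experiment wins;
    otherwise monomeric.
    """
    states: dict[str, str] = {}
    for table in tables:
        for protein, rec in table.items():
            prev = states.get(protein)
            if rec.state == DEGRADED or prev == DEGRADED:
                states[protein] = DEGRADED
            elif rec.state == COMPLEXED or prev == COMPLEXED:
                states[protein] = COMPLEXED
            else:
                states[protein] = MONOMERIC
    return states


# ---------------------------------------------------------------------------
# I/O helpers for the text formats used by fixtures and the CLI
# ---------------------------------------------------------------------------

def write_standards(path, standards: Iterable[tuple[str, float, float]]) -> None:
    """Write (name, mass_kda, peak_fraction) rows as TSV."""
    df = pd.DataFrame(standards, columns=["standard", "mass_kda", "peak_fraction"])
    df.to_csv(path, sep="\t", index=False)


def read_standards(path) -> list[tuple[float, float]]:
    """Read a standards TSV; returns (mass_kda, peak_fraction) pairs."""
    df = pd.read_csv(Path(path), sep="\t")
    return [(float(m), float(f)) for m, f in zip(df["mass_kda"], df["peak_fraction"])]


def write_monomer_masses(path, masses: Mapping[str, float]) -> None:
    df = pd.DataFrame(sorted(masses.items()), columns=["protein_id", "mass_kda"])
    df.to_csv(path, sep="\t", index=False)


def read_monomer_masses(path) -> dict[str, float]:
    df = pd.read_csv(Path(path), sep="\t")
    return {str(p): float(m) for p, m in zip(df["protein_id"], df["mass_kda"])}
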