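"""Synthetic co-fractionation experiments with planted complexes.

Generates the post-identification view of a CoFrac-MS study: per-experiment
protein x fraction spectral-count matrices for SEC, IEX, and SDGC
separations, together with the ground truth (complex membership, monomer
masses, degraded proteins) needed to evaluate every downstream stage.

The emulated physics, per technique:

* SEC / SDGC separate by native size: a species' peak fraction is the
  inverse of the column's log-linear mass calibration evaluated at its
  eluting mass (assembly mass for complex members, monomer mass for
  monomers, a sub-monomer mass for degraded proteins).
* IEX separates by charge, which is unrelated to mass here: each complex
  draws one peak fraction uniformly at random, shared by its members, so
  IEX resolves complexes that co-elute on the size-based columns.

Counts are Poisson draws around a Gaussian elution kernel scaled to a
per-complex (log-normal) abundance, thinned by per-cell dropout and
contaminated by a low Poisson background — the qualitative noise structure
of spectral counting.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import calibration
from .errors import ConfigurationError
from .profiles import ProfileMatrix, write_fraction_table

#: Eluting mass of a degraded protein, as a fraction of its monomer mass.
#: 0.4x puts the true Rapp at 0.4, on the degraded side of the 0.5 rule.
DEGRADED_MASS_FACTOR = 0.4

#: Complexes of size >= 3 are assembled so every member's assembly-to-monomer
#: mass ratio is at least this, keeping planted oligomers detectably above
#: the Rapp >= 2 rule with margin for the integer fraction grid. (A size-2
#: heterodimer cannot exceed 2x its heavier member, so no constraint there.)
MIN_ASSEMBLY_RATIO = 2.5

DEFAULT_EXPERIMENTS = (("SEC", 24), ("SEC", 45), ("IEX", 43), ("SDGC", 24))

MIN_FRACTIONS = 10

# fixture file names
MONOMER_MASS_FILE = "monomer_masses.tsv"
REFERENCE_COMPLEX_FILE = "reference_complexes.tsv"
TRUE_PAIR_FILE = "true_pairs.tsv"
GROUND_TRUTH_FILE = "ground_truth.json"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic dataset."""

    n_complexes: int = 50
    n_monomers: int = 150
    complex_size_range: tuple[int, int] = (2, 10)
    complex_size_geom_p: float = 0.3
    mass_range_kda: tuple[float, float] = (10.0, 150.0)
    experiments: tuple[tuple[str, int], ...] = DEFAULT_EXPERIMENTS
    elution_sigma: float = 1.2
    mean_total_counts: float = 150.0
    dropout_prob: float = 0.2
    degraded_fraction: float = 0.05
    background_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_complexes < 0 or self.n_monomers < 0:
            raise ConfigurationError("counts must be non-negative")
        if not self.experiments:
            raise ConfigurationError("at least one experiment is required")
        for technique, n_fractions in self.experiments:
            if technique not in ("SEC", "IEX", "SDGC"):
                raise ConfigurationError(f"unknown technique {technique!r}")
            if n_fractions < MIN_FRACTIONS:
                raise ConfigurationError(
                    f"n_fractions must be >= {MIN_FRACTIONS}, got {n_fractions}"
                )
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("complex sizes must satisfy 2 <= lo <= hi")
        for p, name in (
            (self.dropout_prob, "dropout_prob"),
            (self.degraded_fraction, "degraded_fraction"),
            (self.complex_size_geom_p, "complex_size_geom_p"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        if self.elution_sigma <= 0:
            raise ConfigurationError("elution_sigma must be > 0")
        if self.mean_total_counts <= 0 or self.background_rate < 0:
            raise ConfigurationError("count rates must be positive")
        if self.mass_range_kda[0] <= 0 or self.mass_range_kda[1] < self.mass_range_kda[0]:
            raise ConfigurationError("invalid mass range")

    def experiment_ids(self) -> list[str]:
        counters: dict[str, int] = {}
        ids = []
        for technique, _ in self.experiments:
            counters[technique] = counters.get(technique, 0) + 1
            ids.append(f"{technique}{counters[technique]}")
        return ids


@dataclass(frozen=True)
class PlantedComplex:
    name: str
    members: tuple[str, ...]
    mass_kda: float
    abundance: float


@dataclass
class GroundTruth:
    """Planted population: who is in which complex, masses, degraded flags."""

    proteins: list[str]
    monomer_mass: dict[str, float]
    complexes: list[PlantedComplex]
    monomers: frozenset[str]
    degraded: frozenset[str]
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        self._complex_of = {
            p: c for c in self.complexes for p in c.members
        }

    def complex_of(self, protein: str) -> PlantedComplex | None:
        return self._complex_of.get(protein)

    def planted_state(self, protein: str) -> str:
        """The generative state: degraded dominates complex membership."""
        if protein in self.degraded:
            return calibration.DEGRADED
        if protein in self._complex_of:
            return calibration.COMPLEXED
        return calibration.MONOMERIC

    def eluting_mass(self, protein: str) -> float:
        """Mass at which the protein's dominant species elutes on size columns."""
        mono = self.monomer_mass[protein]
        if protein in self.degraded:
            return DEGRADED_MASS_FACTOR * mono
        cpx = self._complex_of.get(protein)
        return cpx.mass_kda if cpx is not None else mono

    def true_pairs(self) -> list[tuple[str, str]]:
        """All within-complex pairs, lexicographically ordered."""
        pairs = set()
        for cpx in self.complexes:
            for a, b in itertools.combinations(sorted(cpx.members), 2):
                pairs.add((a, b))
        return sorted(pairs)

    def reference_complexes(self) -> dict[str, frozenset[str]]:
        return {c.name: frozenset(c.members) for c in self.complexes}


def _sample_size(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    lo, hi = cfg.complex_size_range
    if lo == hi:
        return lo
    while True:
        s = lo + int(rng.geometric(cfg.complex_size_geom_p)) - 1
        if s <= hi:
            return s


def _sample_member_masses(
    rng: np.random.Generator, size: int, cfg: SimulationConfig
) -> np.ndarray:
    lo, hi = cfg.mass_range_kda
    if size == 2:
        return rng.uniform(lo, hi, 2)
    for _ in range(500):
        masses = rng.uniform(lo, hi, size)
        if masses.sum() >= MIN_ASSEMBLY_RATIO * masses.max():
            return masses
    # pathological ranges only: fall back to an equal-mass assembly
    return np.full(size, float(rng.uniform(lo, hi)))


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted population (deterministic for a fixed seed)."""
    config.validate()
    rng = np.random.default_rng((config.seed, 0))
    log_mu = math.log(config.mean_total_counts)

    proteins: list[str] = []
    monomer_mass: dict[str, float] = {}
    abundance: dict[str, float] = {}
    complexes: list[PlantedComplex] = []
    counter = itertools.count(1)

    for c in range(config.n_complexes):
        size = _sample_size(rng, config)
        masses = _sample_member_masses(rng, size, config)
        members = tuple(f"P{next(counter):04d}" for _ in range(size))
        cpx_abundance = float(rng.lognormal(log_mu, 1.0))
        for pid, m in zip(members, masses):
            proteins.append(pid)
            monomer_mass[pid] = float(m)
            abundance[pid] = cpx_abundance
        complexes.append(
            PlantedComplex(
                name=f"CPX{c + 1:03d}",
                members=members,
                mass_kda=float(masses.sum()),
                abundance=cpx_abundance,
            )
        )

    monomers = []
    for _ in range(config.n_monomers):
        pid = f"P{next(counter):04d}"
        proteins.append(pid)
        monomer_mass[pid] = float(rng.uniform(*config.mass_range_kda))
        abundance[pid] = float(rng.lognormal(log_mu, 1.0))
        monomers.append(pid)

    degraded = frozenset(
        p for p in proteins if rng.random() < config.degraded_fraction
    )
    return GroundTruth(
        proteins=proteins,
        monomer_mass=monomer_mass,
        complexes=complexes,
        monomers=frozenset(monomers),
        degraded=degraded,
        abundance=abundance,
    )


def expected_profile(
    center: float, n_fractions: int, sigma: float, abundance: float
) -> np.ndarray:
    """Noise-free expected counts: Gaussian kernel scaled to `abundance`."""
    fr = np.arange(1, n_fractions + 1, dtype=float)
    kernel = np.exp(-((fr - center) ** 2) / (2.0 * sigma**2))
    total = kernel.sum()
    if total == 0:
        return np.zeros(n_fractions)
    return abundance * kernel / total


def elution_centers(
    truth: GroundTruth,
    technique: str,
    n_fractions: int,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Peak fraction per protein for one experiment.

    SEC/SDGC centers come from the column's calibration line at each
    protein's eluting mass; IEX centers are uniform per complex (shared by
    non-degraded members) and uniform per protein otherwise. Degraded
    proteins never share their complex's center.
    """
    if technique not in ("SEC", "IEX", "SDGC"):
        raise ConfigurationError(f"unknown technique {technique!r}")
    if n_fractions < MIN_FRACTIONS:
        raise ConfigurationError(f"n_fractions must be >= {MIN_FRACTIONS}")
    centers: dict[str, float] = {}
    if technique == "IEX":
        if rng is None:
            rng = np.random.default_rng(0)
        complex_center = {
            c.name: float(rng.uniform(1, n_fractions)) for c in truth.complexes
        }
        for p in truth.proteins:
            cpx = truth.complex_of(p)
            if cpx is not None and p not in truth.degraded:
                centers[p] = complex_center[cpx.name]
            else:
                centers[p] = float(rng.uniform(1, n_fractions))
    else:
        model = calibration.true_calibration(n_fractions)
        for p in truth.proteins:
            centers[p] = float(
                np.clip(model.fraction_at(truth.eluting_mass(p)), 1, n_fractions)
            )
    return centers


def simulate_experiment(
    truth: GroundTruth,
    technique: str,
    n_fractions: int,
    config: SimulationConfig,
    experiment_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> ProfileMatrix:
    """Draw one experiment's spectral-count matrix."""
    if rng is None:
        rng = np.random.default_rng((config.seed, 1))
    if experiment_id is None:
        experiment_id = f"{technique}1"
    centers = elution_centers(truth, technique, n_fractions, rng=rng)
    n = len(truth.proteins)
    counts = np.zeros((n, n_fractions), dtype=np.int64)
    for i, p in enumerate(truth.proteins):
        lam = expected_profile(
            centers[p], n_fractions, config.elution_sigma, truth.abundance[p]
        )
        obs = rng.poisson(lam)
        if config.dropout_prob > 0:
            obs = np.where(rng.random(n_fractions) < config.dropout_prob, 0, obs)
        if config.background_rate > 0:
            obs = obs + rng.poisson(config.background_rate, n_fractions)
        counts[i] = obs
    return ProfileMatrix(
        experiment_id=experiment_id,
        technique=technique,
        proteins=list(truth.proteins),
        counts=counts,
    )


def simulate_dataset(
    truth: GroundTruth, config: SimulationConfig
) -> list[ProfileMatrix]:
    """All configured experiments from a single seeded random stream."""
    rng = np.random.default_rng((config.seed, 1))
    matrices = []
    for exp_id, (technique, n_fractions) in zip(
        config.experiment_ids(), config.experiments
    ):
        matrices.append(
            simulate_experiment(
                truth, technique, n_fractions, config, experiment_id=exp_id, rng=rng
            )
        )
    return matrices


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(
    truth: GroundTruth,
    matrices: Sequence[ProfileMatrix],
    directory,
) -> dict[str, Path]:
    """Write a complete fixture in the text formats the readers consume.

    Emits fraction tables, the monomer-mass table, calibration standards for
    every SEC experiment, the reference-complex file, the true-pair list,
    and a JSON dump of the full ground truth.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for m in matrices:
        p = directory / f"{m.experiment_id}_fractions.tsv"
        write_fraction_table(m, p)
        paths[f"matrix:{m.experiment_id}"] = p
        if m.technique == "SEC":
            model = calibration.true_calibration(m.n_fractions)
            rows = [
                (name, mass, float(round(np.clip(model.fraction_at(mass), 1, m.n_fractions))))
                for name, mass in calibration.DEFAULT_STANDARDS
            ]
            sp = directory / f"{m.experiment_id}_standards.tsv"
            calibration.write_standards(sp, rows)
            paths[f"standards:{m.experiment_id}"] = sp

    mp = directory / MONOMER_MASS_FILE
    calibration.write_monomer_masses(mp, truth.monomer_mass)
    paths["monomer_masses"] = mp

    cp = directory / REFERENCE_COMPLEX_FILE
    with open(cp, "w") as fh:
        for cpx in truth.complexes:
            fh.write("\t".join([cpx.name, *sorted(cpx.members)]) + "\n")
    paths["reference_complexes"] = cp

    tp = directory / TRUE_PAIR_FILE
    with open(tp, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in truth.true_pairs():
            fh.write(f"{a}\t{b}\n")
    paths["true_pairs"] = tp

    gt = directory / GROUND_TRUTH_FILE
    payload = {
        "proteins": truth.proteins,
        "monomer_mass": truth.monomer_mass,
        "complexes": [asdict(c) for c in truth.complexes],
        "monomers": sorted(truth.monomers),
        "degraded": sorted(truth.degraded),
        "abundance": truth.abundance,
    }
    gt.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["ground_truth"] = gt
    return paths


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        proteins=list(payload["proteins"]),
        monomer_mass={k: float(v) for k, v in payload["monomer_mass"].items()},
        complexes=[
            PlantedComplex(
                name=c["name"],
                members=tuple(c["members"]),
                mass_kda=float(c["mass_kda"]),
                abundance=float(c["abundance"]),
            )
            for c in payload["complexes"]
        ],
        monomers=frozenset(payload["monomers"]),
        degraded=frozenset(payload["degraded"]),
        abundance={k: float(v) for k, v in payload["abundance"].items()},
    )
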