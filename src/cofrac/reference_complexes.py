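"""Gold-standard complex sets and labeled training pairs.

A curated set of known complexes supplies supervision: a candidate pair is a
positive example if its two members co-occur in at least one reference
complex, a negative example if each member is annotated to some reference
complex but the two never share one, and unlabeled otherwise. Cross-complex
pairs vastly outnumber co-complex pairs, so negatives are subsampled to a
fixed ratio. Cross-validation folds are assigned at the level of whole
complexes so no complex contributes pairs to both train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, UsageError

log = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ReferenceComplexSet:
    """Named reference complexes (member-id sets)."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if len(members) < 2:
                raise FormatError(f"complex {name!r} has fewer than 2 members")

    def membership(self) -> dict[str, set[str]]:
        """protein id -> set of complex names containing it."""
        out: dict[str, set[str]] = {}
        for name, members in self.complexes.items():
            for p in members:
                out.setdefault(p, set()).add(name)
        return out

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass(frozen=True)
class LabeledPairSet:
    positives: frozenset[Pair]
    negatives: frozenset[Pair]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise UsageError("a pair cannot be both positive and negative")


def read_complex_file(path, universe: Iterable[str] | None = None) -> ReferenceComplexSet:
    """Read a one-complex-per-line TSV (name, then member ids).

    If `universe` is given, members are intersected with it; complexes that
    shrink below two members are dropped with a warning.
    """
    path = Path(path)
    universe_set = set(universe) if universe is not None else None
    complexes: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        name, members = fields[0], fields[1:]
        if name in complexes:
            raise FormatError(f"{path}:{lineno}: duplicate complex name {name!r}")
        member_set = set(members)
        if universe_set is not None:
            member_set &= universe_set
        if len(member_set) < 2:
            log.warning(
                "complex %s dropped: %d member(s) after intersection",
                name,
                len(member_set),
            )
            continue
        complexes[name] = frozenset(member_set)
    return ReferenceComplexSet(complexes)


def write_complex_file(complexes: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(complexes):
            fh.write("\t".join([name, *sorted(complexes[name])]) + "\n")


def derive_labels(
    refset: ReferenceComplexSet,
    candidate_pairs: Iterable[Pair],
    max_negative_ratio: float = 5.0,
    seed: int = 0,
) -> LabeledPairSet:
    """Label candidate pairs against the reference set.

    Negatives are subsampled (seeded) to at most `max_negative_ratio` times
    the number of positives; pairs with an unannotated member stay unlabeled.
    """
    if len(refset) == 0:
        raise UsageError("empty reference complex set")
    membership = refset.membership()
    positives: set[Pair] = set()
    negatives: set[Pair] = set()
    for a, b in candidate_pairs:
        pair = canonical_pair(a, b)
        ca = membership.get(pair[0])
        cb = membership.get(pair[1])
        if ca is None or cb is None:
            continue
        if ca & cb:
            positives.add(pair)
        else:
            negatives.add(pair)
    if positives and len(negatives) > max_negative_ratio * len(positives):
        rng = np.random.default_rng(seed)
        keep = rng.choice(
            len(negatives),
            size=int(max_negative_ratio * len(positives)),
            replace=False,
        )
        ordered = sorted(negatives)
        negatives = {ordered[i] for i in keep}
    return LabeledPairSet(frozenset(positives), frozenset(negatives))


def complex_level_folds(
    refset: ReferenceComplexSet, k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Assign whole complexes to k folds, deterministically under `seed`."""
    names = sorted(refset.complexes)
    if k > len(names):
        raise UsageError(f"k={k} exceeds number of complexes ({len(names)})")
    if k < 2:
        raise UsageError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    return {names[idx]: int(i % k) for i, idx in enumerate(order)}


def assign_pair_folds(
    labels: LabeledPairSet,
    refset: ReferenceComplexSet,
    folds: Mapping[str, int],
) -> dict[Pair, int]:
    """Map every labeled pair to one fold.

    A positive pair inherits the fold of the first (name-sorted) complex
    containing both members, so all of a complex's positive pairs stay in
    one fold. A negative pair inherits the fold of the first complex of its
    first member.
    """
    membership = refset.membership()
    out: dict[Pair, int] = {}
    for pair in labels.positives:
        common = sorted(membership[pair[0]] & membership[pair[1]])
        out[pair] = folds[common[0]]
    for pair in labels.negatives:
        out[pair] = folds[sorted(membership[pair[0]])[0]]
    return out
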