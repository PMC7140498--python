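"""Matched molecular pairs: fragmentation, pair indexing, transform compilation.

The miner follows the fragment-and-index strategy: every acyclic single bond
between heavy atoms is cut, splitting the molecule into a *constant* part
(key) and a *variable* fragment (value), both written as canonical SMILES
with mapped dummy-atom attachment points. Compounds sharing a constant key
but differing in the variable fragment form a matched molecular pair — two
structures identical except for a single-site substitution — and the
(left-fragment → right-fragment) rewrite connecting them is the transform.
Transforms are aggregated over all supporting pairs with half-life shift
statistics, and validated prospectively on a random 70:30 train/test split.

Single cuts are the default; two-bond cuts (variable fragment = the linker
carrying both attachment points) are available behind ``n_cuts=2``.
"""

from __future__ import annotations

import csv
import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from cytostab.halflife import ShiftCategory, classify_pair_shift
from cytostab.standardize import CompoundRecord

logger = logging.getLogger(__name__)

MAX_VARIABLE_HEAVY_ATOMS = 13


@dataclass(frozen=True)
class Fragmentation:
    """One cut of a molecule: constant ``key`` plus variable ``value``."""

    key: str  # canonical SMILES of the constant part, mapped dummies
    value: str  # canonical SMILES of the variable fragment
    n_cuts: int


@dataclass(frozen=True)
class MatchedPair:
    """Two compounds differing only at a single site."""

    left: CompoundRecord
    right: CompoundRecord
    constant_key: str
    lhs_frag: str
    rhs_frag: str
    delta_t_half: float  # right − left, minutes (capped values enter as 120)
    shift: ShiftCategory


@dataclass
class Transform:
    """A directional left-fragment → right-fragment rewrite rule."""

    lhs_frag: str
    rhs_frag: str
    frequency: int
    shifts: list[ShiftCategory]
    mean_delta: float
    geometric_mean_fold: float  # over pairs with neither member capped; nan if none

    @property
    def shift_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in ShiftCategory.LABELS}
        for s in self.shifts:
            counts[s.label] += 1
        return counts


def _heavy_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0)


def _canonical_fragment(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    bonds = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        bonds.append(bond.GetIdx())
    return bonds


def _variable_allowed(n_var: int, n_const: int) -> bool:
    # Variable fragment stays the minority part and chemically interpretable.
    return n_var <= MAX_VARIABLE_HEAVY_ATOMS and n_var <= n_const


def _single_cut_fragmentations(mol: Chem.Mol) -> set[Fragmentation]:
    out: set[Fragmentation] = set()
    for bidx in _cuttable_bonds(mol):
        frag = Chem.FragmentOnBonds(mol, [bidx], addDummies=True, dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:
            continue
        smis = []
        sizes = []
        ok = True
        for p in pieces:
            for a in p.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetAtomMapNum(1)
            try:
                Chem.SanitizeMol(p)
            except Exception:
                ok = False
                break
            smis.append(_canonical_fragment(p))
            sizes.append(_heavy_atoms(p))
        if not ok:
            continue
        for (i, j) in ((0, 1), (1, 0)):
            if _variable_allowed(n_var=sizes[j], n_const=sizes[i]):
                out.add(Fragmentation(key=smis[i], value=smis[j], n_cuts=1))
    return out


def _double_cut_fragmentations(mol: Chem.Mol) -> set[Fragmentation]:
    out: set[Fragmentation] = set()
    bonds = _cuttable_bonds(mol)
    n_parent = _heavy_atoms(mol)
    for b1, b2 in itertools.combinations(bonds, 2):
        frag = Chem.FragmentOnBonds(
            mol, [b1, b2], addDummies=True, dummyLabels=[(1, 1), (2, 2)]
        )
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(pieces) != 3:
            continue  # both cuts on the same branch; linear 3-piece splits only
        variable = None
        constant = []
        ok = True
        for p in pieces:
            labels = set()
            for a in p.GetAtoms():
                if a.GetAtomicNum() == 0:
                    labels.add(a.GetIsotope())
                    a.SetAtomMapNum(a.GetIsotope())
                    a.SetIsotope(0)
            try:
                Chem.SanitizeMol(p)
            except Exception:
                ok = False
                break
            if len(labels) == 2:
                variable = p
            else:
                constant.append(p)
        if not ok or variable is None or len(constant) != 2:
            continue
        n_var = _heavy_atoms(variable)
        if not _variable_allowed(n_var, n_parent - n_var):
            continue
        key = _canonical_fragment(Chem.CombineMols(constant[0], constant[1]))
        out.add(
            Fragmentation(key=key, value=_canonical_fragment(variable), n_cuts=2)
        )
    return out


def fragment_molecule(
    mol: Chem.Mol | str, n_cuts: int = 1
) -> list[Fragmentation]:
    """Enumerate all fragmentations of a standardized molecule.

    Cuts acyclic single bonds between heavy atoms only; the variable fragment
    must have ≤ 13 heavy atoms and be no larger than the constant part.
    Output is deterministic, canonical, and free of duplicates. A molecule
    with no cuttable bond yields an empty list.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
    if mol is None:
        raise ValueError("invalid molecule")
    frags = _single_cut_fragmentations(mol)
    if n_cuts >= 2:
        frags |= _double_cut_fragmentations(mol)
    return sorted(frags, key=lambda f: (f.n_cuts, f.key, f.value))


def reassemble(key: str, value: str) -> Chem.Mol:
    """Rejoin a constant key with a variable fragment at the mapped dummies.

    Inverse of :func:`fragment_molecule` up to identity key: reassembling a
    Fragmentation reproduces the parent molecule's InChIKey.
    """
    const = Chem.MolFromSmiles(key)
    var = Chem.MolFromSmiles(value)
    if const is None or var is None:
        raise ValueError(f"invalid fragment SMILES: {key!r} / {value!r}")
    mol = Chem.molzip(const, var)
    Chem.SanitizeMol(mol)
    return mol


def index_pairs(
    records: Sequence[CompoundRecord], n_cuts: int = 1
) -> list[MatchedPair]:
    """Find all matched molecular pairs among deduplicated records.

    Fragmentations are grouped by constant key; every unordered pair of
    distinct compounds sharing a key with different variable fragments
    yields two directional pairs (A→B and B→A). Equivalent to the all-pairs
    single-site-difference brute force on small sets.
    """
    index: dict[str, list[tuple[str, str]]] = {}
    by_key: dict[str, CompoundRecord] = {}
    for rec in records:
        by_key[rec.inchikey] = rec
        for f in fragment_molecule(rec.smiles_std, n_cuts=n_cuts):
            index.setdefault(f.key, []).append((rec.inchikey, f.value))

    emitted: set[tuple] = set()
    pairs: list[MatchedPair] = []
    for const_key in sorted(index):
        entries = sorted(set(index[const_key]))
        for (ik_a, val_a), (ik_b, val_b) in itertools.combinations(entries, 2):
            if ik_a == ik_b or val_a == val_b:
                continue
            for (ik_l, v_l), (ik_r, v_r) in (
                ((ik_a, val_a), (ik_b, val_b)),
                ((ik_b, val_b), (ik_a, val_a)),
            ):
                sig = (ik_l, ik_r, const_key, v_l, v_r)
                if sig in emitted:
                    continue
                emitted.add(sig)
                left, right = by_key[ik_l], by_key[ik_r]
                pairs.append(
                    MatchedPair(
                        left=left,
                        right=right,
                        constant_key=const_key,
                        lhs_frag=v_l,
                        rhs_frag=v_r,
                        delta_t_half=right.t_half - left.t_half,
                        shift=classify_pair_shift(left.half_life, right.half_life),
                    )
                )
    return pairs


def compile_transforms(pairs: Sequence[MatchedPair]) -> list[Transform]:
    """Aggregate directional pairs into unique transformation rules.

    One transform per canonical (lhs_frag, rhs_frag); frequency counts the
    supporting pairs, ``mean_delta`` is the arithmetic mean of Δt½ (capped
    values entering as 120) and ``geometric_mean_fold`` is exp(mean log fold)
    over pairs with neither member capped.
    """
    groups: dict[tuple[str, str], list[MatchedPair]] = {}
    for p in pairs:
        groups.setdefault((p.lhs_frag, p.rhs_frag), []).append(p)
    transforms = []
    for (lhs, rhs) in sorted(groups):
        members = groups[(lhs, rhs)]
        deltas = [p.delta_t_half for p in members]
        log_folds = [
            math.log(p.right.t_half / p.left.t_half)
            for p in members
            if not (p.left.capped or p.right.capped)
        ]
        transforms.append(
            Transform(
                lhs_frag=lhs,
                rhs_frag=rhs,
                frequency=len(members),
                shifts=[p.shift for p in members],
                mean_delta=float(np.mean(deltas)),
                geometric_mean_fold=(
                    math.exp(float(np.mean(log_folds))) if log_folds else float("nan")
                ),
            )
        )
    transforms.sort(key=lambda t: (-t.frequency, t.lhs_frag, t.rhs_frag))
    return transforms


def count_unique_transforms(transforms: Sequence[Transform]) -> int:
    """Number of unique rules, collapsing mirror-image (A→B / B→A) pairs."""
    seen = set()
    for t in transforms:
        seen.add(frozenset((t.lhs_frag, t.rhs_frag)))
    return len(seen)


def frequency_histogram(transforms: Sequence[Transform]) -> dict[str, int]:
    """Counts of transforms with at least 1, 2 and 3 supporting examples."""
    return {
        ">=1": sum(1 for t in transforms if t.frequency >= 1),
        ">=2": sum(1 for t in transforms if t.frequency >= 2),
        ">=3": sum(1 for t in transforms if t.frequency >= 3),
    }


def split_train_test(
    records: Sequence[CompoundRecord], ratio: float = 0.7, seed: int = 0
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Random train/test partition that is a pure function of (ids, ratio, seed).

    Records are keyed and ordered by InChIKey before shuffling, so two
    species tables holding the same compounds split identically under the
    same seed — the property the study relies on to keep the human and
    mouse train/test compositions aligned.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    ordered = sorted(records, key=lambda r: r.inchikey)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ordered))
    n_train = round(ratio * len(ordered))
    train_idx = set(perm[:n_train].tolist())
    train = [r for i, r in enumerate(ordered) if i in train_idx]
    test = [r for i, r in enumerate(ordered) if i not in train_idx]
    return train, test


@dataclass
class ProspectiveReport:
    """Outcome of applying train-derived transforms to the held-out split."""

    n_common_transforms: int
    n_test_pairs: int
    n_compounds_affected: int
    fraction_fold_ge_1_5: float  # among non-inconclusive test pairs
    n_unstable_to_stable: int


def prospective_validate(
    train_transforms: Sequence[Transform],
    test_records: Sequence[CompoundRecord],
    n_cuts: int = 1,
) -> ProspectiveReport:
    """Validate train-set transforms on the held-out test records.

    Mines pairs from the test split, keeps those supported by a transform
    also present in the training set, and reports how often the measured t½
    rose by ≥ 1.5-fold and how many left-side compounds converted from
    unstable to stable. Pairs with both members capped are excluded from the
    fold-fraction denominator.
    """
    train_keys = {(t.lhs_frag, t.rhs_frag) for t in train_transforms}
    test_pairs = index_pairs(test_records, n_cuts=n_cuts)
    common_pairs = [p for p in test_pairs if (p.lhs_frag, p.rhs_frag) in train_keys]
    if not common_pairs:
        logger.warning("no transforms common to train and test splits")
        return ProspectiveReport(0, 0, 0, 0.0, 0)
    common_keys = {(p.lhs_frag, p.rhs_frag) for p in common_pairs}
    conclusive = [p for p in common_pairs if p.shift.label != "inconclusive"]
    n_pos = sum(1 for p in conclusive if p.shift.label == "positive")
    conversions = sum(
        1
        for p in common_pairs
        if p.left.stability_class == "unstable"
        and p.right.stability_class == "stable"
    )
    return ProspectiveReport(
        n_common_transforms=len(common_keys),
        n_test_pairs=len(common_pairs),
        n_compounds_affected=len({p.left.inchikey for p in common_pairs}),
        fraction_fold_ge_1_5=(n_pos / len(conclusive)) if conclusive else 0.0,
        n_unstable_to_stable=conversions,
    )


# ---------------------------------------------------------------------------
# I/O

def write_transforms_csv(transforms: Sequence[Transform], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "lhs", "rhs", "frequency", "n_pos", "n_neg", "n_noshift",
                "n_inconclusive", "mean_delta_min", "geomean_fold",
            ]
        )
        for t in transforms:
            c = t.shift_counts
            writer.writerow(
                [
                    t.lhs_frag, t.rhs_frag, t.frequency, c["positive"], c["negative"],
                    c["no_shift"], c["inconclusive"],
                    f"{t.mean_delta:.3f}",
                    "" if math.isnan(t.geometric_mean_fold) else f"{t.geometric_mean_fold:.4f}",
                ]
            )


def read_transforms_csv(path: str | Path) -> list[Transform]:
    transforms = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            counts = {
                "positive": int(row["n_pos"]),
                "negative": int(row["n_neg"]),
                "no_shift": int(row["n_noshift"]),
                "inconclusive": int(row["n_inconclusive"]),
            }
            shifts = [
                ShiftCategory(label, 1.0)
                for label, n in counts.items()
                for _ in range(n)
            ]
            transforms.append(
                Transform(
                    lhs_frag=row["lhs"],
                    rhs_frag=row["rhs"],
                    frequency=int(row["frequency"]),
                    shifts=shifts,
                    mean_delta=float(row["mean_delta_min"]),
                    geometric_mean_fold=(
                        float(row["geomean_fold"]) if row["geomean_fold"] else float("nan")
                    ),
                )
            )
    return transforms


def write_pairs_csv(pairs: Sequence[MatchedPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "left_inchikey", "right_inchikey", "constant_key", "lhs", "rhs",
                "left_t_half", "right_t_half", "delta_t_half", "shift", "fold",
            ]
        )
        for p in pairs:
            writer.writerow(
                [
                    p.left.inchikey, p.right.inchikey, p.constant_key,
                    p.lhs_frag, p.rhs_frag,
                    f"{p.left.t_half:.2f}", f"{p.right.t_half:.2f}",
                    f"{p.delta_t_half:.2f}", p.shift.label,
                    f"{p.shift.fold_change:.4f}",
                ]
            )
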