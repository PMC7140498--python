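"""Apply mined transforms across a library and judge transforms by outcome.

A transform's left fragment is matched against each library molecule by
re-enumerating the molecule's fragmentations; every site carrying the left
fragment is rewritten to the right fragment (one product per site, single-site
rewrites only). Products found in the library by InChIKey become candidate
pairs; a QSAR model then prioritizes pairs whose left member is predicted
unstable, and measured shifts aggregate into a per-transform verdict:

* valuable   — at least one positive shift and no negative shift
* not_useful — at least as many negative as positive shifts (or nothing
  but no-shifts and fewer no-shifts than negatives)
* neutral    — negatives present but outnumbered by no-shifts (and fewer
  negatives than positives)
* undetermined — every example inconclusive (both members above the cap)
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem

from cytostab.halflife import HalfLife, ShiftCategory, classify_pair_shift
from cytostab.mmpa import MatchedPair, Transform, fragment_molecule, reassemble
from cytostab.standardize import CompoundRecord, compute_inchikey, standardize_structure

logger = logging.getLogger(__name__)

VERDICT_LABELS = ("valuable", "neutral", "not_useful", "undetermined")


@dataclass(frozen=True)
class CandidatePair:
    """A library pair (left, transformed-left found in library)."""

    left: CompoundRecord
    right: CompoundRecord
    transform_id: str
    left_pred_unstable: bool | None = None
    left_score: float | None = None
    measured_shift: ShiftCategory | None = None


@dataclass(frozen=True)
class TransformVerdict:
    """Usefulness label for a transform given its observed shift counts."""

    label: str
    n_pos: int
    n_neg: int
    n_noshift: int
    n_inconclusive: int


def apply_transform(transform: Transform, mol: Chem.Mol | str) -> list[Chem.Mol]:
    """Rewrite every site of ``mol`` matching the transform's left fragment.

    Matching goes through the same fragmentation enumeration used by the
    miner, which guarantees that applying a mined transform to its pair's
    left compound reconstructs the right compound. Products are standardized
    and deduplicated by InChIKey; chemically invalid products are dropped
    with a log line. A molecule without the left fragment yields ``[]``.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
    if mol is None:
        raise ValueError("invalid molecule")
    n_cuts = transform.lhs_frag.count("*")
    products: list[Chem.Mol] = []
    seen: set[str] = set()
    for frag in fragment_molecule(mol, n_cuts=n_cuts):
        if frag.value != transform.lhs_frag:
            continue
        try:
            product = reassemble(frag.key, transform.rhs_frag)
            smi = standardize_structure(Chem.MolToSmiles(product))
            key = compute_inchikey(smi)
        except Exception as err:  # valence violations etc.
            logger.info("dropped invalid product at key %s: %s", frag.key, err)
            continue
        if key in seen:
            continue
        seen.add(key)
        products.append(Chem.MolFromSmiles(smi))
    return products


def transform_id(t: Transform) -> str:
    return f"{t.lhs_frag}>>{t.rhs_frag}"


def match_library(
    transform: Transform,
    library: Mapping[str, CompoundRecord] | Sequence[CompoundRecord],
) -> list[CandidatePair]:
    """Apply a transform across the library and keep products found in it.

    ``library`` may be a list of records or a mapping inchikey → record.
    A pair is emitted iff the product's InChIKey is a library member;
    duplicates collapse.
    """
    if not isinstance(library, Mapping):
        library = {r.inchikey: r for r in library}
    tid = transform_id(transform)
    pairs: list[CandidatePair] = []
    seen: set[tuple[str, str]] = set()
    for rec in sorted(library.values(), key=lambda r: r.inchikey):
        for product in apply_transform(transform, rec.smiles_std):
            key = Chem.MolToInchiKey(product)
            right = library.get(key)
            if right is None or right.inchikey == rec.inchikey:
                continue
            sig = (rec.inchikey, right.inchikey)
            if sig in seen:
                continue
            seen.add(sig)
            pairs.append(
                CandidatePair(
                    left=rec,
                    right=right,
                    transform_id=tid,
                    measured_shift=classify_pair_shift(
                        rec.half_life, right.half_life
                    ),
                )
            )
    return pairs


def prioritize_pairs(pairs: Sequence[CandidatePair], model, k: int) -> list[CandidatePair]:
    """Keep pairs whose left member the QSAR model predicts unstable; rank.

    Ranking: descending predicted instability score of the left compound,
    tie-broken by the larger left−right score gap, then lexicographic
    InChIKeys. Returns at most ``k`` pairs.
    """
    if not getattr(model, "is_fitted", lambda: False)():
        raise ValueError("QSAR model must be trained before prioritization")
    if not pairs:
        return []
    left_scores = model.predict_proba_records([p.left for p in pairs])
    right_scores = model.predict_proba_records([p.right for p in pairs])
    scored = []
    for p, sl, sr in zip(pairs, left_scores, right_scores):
        if sl < 0.5:  # left predicted stable
            continue
        scored.append(
            (
                -sl,
                -(sl - sr),
                p.left.inchikey,
                p.right.inchikey,
                CandidatePair(
                    left=p.left,
                    right=p.right,
                    transform_id=p.transform_id,
                    left_pred_unstable=True,
                    left_score=float(sl),
                    measured_shift=p.measured_shift,
                ),
            )
        )
    scored.sort(key=lambda t: t[:4])
    return [t[4] for t in scored[:k]]


def verdict(shifts: Sequence[ShiftCategory]) -> TransformVerdict:
    """Judge a transform from the shifts of its example pairs.

    Inconclusive examples (both members above the 120 min cap) are excluded
    from every count; if nothing else remains the verdict is undetermined.
    Rules, in order: all positive → valuable; ≥1 positive with no negative →
    valuable; at least as many negatives as positives → not useful; more
    no-shifts than negatives → neutral; otherwise not useful.
    """
    n_pos = sum(1 for s in shifts if s.label == "positive")
    n_neg = sum(1 for s in shifts if s.label == "negative")
    n_noshift = sum(1 for s in shifts if s.label == "no_shift")
    n_inconclusive = sum(1 for s in shifts if s.label == "inconclusive")
    n_concl = n_pos + n_neg + n_noshift
    if n_concl == 0:
        label = "undetermined"
    elif n_pos == n_concl:
        label = "valuable"
    elif n_pos >= 1 and n_neg == 0:
        label = "valuable"
    elif n_neg >= n_pos:
        label = "not_useful"
    elif n_noshift > n_neg:
        label = "neutral"
    else:
        label = "not_useful"
    return TransformVerdict(label, n_pos, n_neg, n_noshift, n_inconclusive)


# ---------------------------------------------------------------------------
# Validation-table accounting (the released table of experimentally tested
# pairs: columns pair_id, side, smiles, t_half_min).

@dataclass
class ValidationCounts:
    """Pair accounting over an experimentally tested validation table."""

    n_pairs: int
    n_positive: int  # fold ≥ 1.5
    n_negative: int
    n_noshift: int
    n_inconclusive: int
    n_unstable_left: int
    n_unstable_to_stable: int


def read_validation_table(path: str | Path) -> list[tuple[str, HalfLife, HalfLife]]:
    """Read a `pair_id,side,smiles,t_half_min` CSV into (id, left, right) rows.

    ``side`` is "left" or "right"; ">120" marks a capped half-life. Pairs
    missing either side are skipped.
    """
    rows: dict[str, dict[str, HalfLife]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = row["t_half_min"].strip()
            if raw.startswith(">"):
                h = HalfLife(120.0, True)
            else:
                v = float(raw)
                h = HalfLife(120.0, True) if v > 120 else HalfLife(v, False)
            rows.setdefault(row["pair_id"], {})[row["side"]] = h
    out = []
    for pid in sorted(rows):
        sides = rows[pid]
        if "left" in sides and "right" in sides:
            out.append((pid, sides["left"], sides["right"]))
    return out


def validation_counts(pairs: Sequence[tuple[str, HalfLife, HalfLife]]) -> ValidationCounts:
    """Recompute shift accounting for a validation table's pairs."""
    n_pos = n_neg = n_ns = n_inc = n_ul = n_conv = 0
    from cytostab.halflife import classify_stability

    for _, left, right in pairs:
        s = classify_pair_shift(left, right)
        if s.label == "positive":
            n_pos += 1
        elif s.label == "negative":
            n_neg += 1
        elif s.label == "no_shift":
            n_ns += 1
        else:
            n_inc += 1
        if classify_stability(left) == "unstable":
            n_ul += 1
            if classify_stability(right) == "stable":
                n_conv += 1
    return ValidationCounts(
        n_pairs=len(pairs),
        n_positive=n_pos,
        n_negative=n_neg,
        n_noshift=n_ns,
        n_inconclusive=n_inc,
        n_unstable_left=n_ul,
        n_unstable_to_stable=n_conv,
    )


def write_candidate_pairs_csv(pairs: Sequence[CandidatePair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["left_id", "right_id", "transform_id", "left_score"])
        for p in pairs:
            writer.writerow(
                [
                    p.left.inchikey,
                    p.right.inchikey,
                    p.transform_id,
                    "" if p.left_score is None else f"{p.left_score:.4f}",
                ]
            )
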