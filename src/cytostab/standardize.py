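"""Structure standardization, identity keys, and class-consistent deduplication.

Raw compound entries (SMILES + half-life) are normalized to a canonical
standardized form — largest organic covalent fragment, charges neutralized
where a proton transfer suffices, functional groups in normal form — keyed by
standard InChIKey, and deduplicated so that an identity key whose entries
disagree on stability class contributes no record at all.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from cytostab.halflife import HalfLife, classify_stability

RDLogger.DisableLog("rdApp.warning")

_UNCHARGER = rdMolStandardize.Uncharger()

CAP_MINUTES = 120.0


class StandardizationError(ValueError):
    """A structure could not be parsed or standardized.

    Carries ``source_id`` so rejection logs can be traced back to the input
    row that produced them.
    """

    def __init__(self, message: str, source_id: str | None = None):
        super().__init__(message)
        self.source_id = source_id


@dataclass(frozen=True)
class RawEntry:
    """One input row: structure plus measured half-life for one species."""

    source_id: str
    structure: str
    t_half: float  # minutes
    species: str  # "human" | "mouse"
    capped: bool = False  # half-life reported as ">120"

    def __post_init__(self):
        if self.t_half <= 0:
            raise ValueError(f"t_half must be positive, got {self.t_half}")
        if self.species not in ("human", "mouse"):
            raise ValueError(f"unknown species {self.species!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """A standardized, identity-keyed compound with stability annotation."""

    inchikey: str
    smiles_std: str
    t_half: float
    capped: bool
    stability_class: str  # "stable" | "unstable"
    species: str
    source_id: str = ""

    @property
    def half_life(self) -> HalfLife:
        return HalfLife(self.t_half, self.capped)


def standardize_structure(raw: str, source_id: str | None = None) -> str:
    """Return the canonical standardized SMILES for ``raw``.

    Pipeline: parse → normalizer cleanup (nitro, N-oxide, azide and related
    functional-group normal forms) → largest organic covalent fragment
    (salt/solvent stripping) → neutralize by proton add/remove.
    Stereochemistry is retained. Idempotent: standardizing the output
    returns the output.

    Raises :class:`StandardizationError` on unparseable input or entries
    with no carbon atom (inorganic-only).
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {raw!r}", source_id)
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)
    mol = _UNCHARGER.uncharge(mol)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        raise StandardizationError(
            f"inorganic-only entry (no carbon): {raw!r}", source_id
        )
    return Chem.MolToSmiles(mol)


def compute_inchikey(smiles_std: str) -> str:
    """Standard 27-character InChIKey of a standardized SMILES.

    Two SMILES of the same structure written with different atom orderings
    yield the same key.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles_std!r}")
    key = Chem.MolToInchiKey(mol)
    if not key or len(key) != 27:
        raise StandardizationError(f"InChIKey generation failed for {smiles_std!r}")
    return key


def make_record(entry: RawEntry) -> CompoundRecord:
    """Standardize one raw entry into a :class:`CompoundRecord`."""
    smi = standardize_structure(entry.structure, entry.source_id)
    key = compute_inchikey(smi)
    t = CAP_MINUTES if entry.capped else entry.t_half
    h = HalfLife(t, entry.capped)
    return CompoundRecord(
        inchikey=key,
        smiles_std=smi,
        t_half=h.value,
        capped=h.capped,
        stability_class=classify_stability(h),
        species=entry.species,
        source_id=entry.source_id,
    )


def standardize_entries(
    entries: Iterable[RawEntry],
) -> tuple[list[CompoundRecord], list[dict]]:
    """Standardize many entries; failures are logged and dropped, never imputed."""
    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    for e in entries:
        try:
            records.append(make_record(e))
        except StandardizationError as err:
            rejects.append({"source_id": e.source_id, "reason": str(err)})
    return records, rejects


def _representative_t_half(group: Sequence[CompoundRecord]) -> HalfLife:
    # Geometric mean of uncapped values; the cap dominates if any member hit it.
    if any(r.capped for r in group):
        return HalfLife(CAP_MINUTES, True)
    gm = math.exp(sum(math.log(r.t_half) for r in group) / len(group))
    return HalfLife(gm, False)


def deduplicate(
    records: Sequence[CompoundRecord],
) -> tuple[list[CompoundRecord], list[dict]]:
    """Collapse records sharing an InChIKey; reject class-inconsistent keys.

    A key is retained only if all of its entries carry the same stability
    class; the surviving record's half-life is the geometric mean of the
    group's uncapped values (capped if any member is capped). Returns
    ``(unique_records, rejection_log)``. Idempotent.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.inchikey not in groups:
            groups[r.inchikey] = []
            order.append(r.inchikey)
        groups[r.inchikey].append(r)

    unique: list[CompoundRecord] = []
    rejects: list[dict] = []
    for key in order:
        group = groups[key]
        classes = {r.stability_class for r in group}
        if len(classes) > 1:
            rejects.append(
                {
                    "inchikey": key,
                    "reason": "stability class disagreement among duplicates",
                    "n_entries": len(group),
                }
            )
            continue
        rep = group[0]
        if len(group) > 1:
            h = _representative_t_half(group)
            rep = replace(
                rep,
                t_half=h.value,
                capped=h.capped,
                stability_class=classify_stability(h),
            )
        unique.append(rep)
    return unique, rejects


# ---------------------------------------------------------------------------
# I/O: CSV dialect `id,smiles,t_half_min,species` (">120" accepted), SDF with
# equivalent tags; output `inchikey,smiles_std,t_half_min,capped,
# stability_class,species`.

def _parse_t_half(text: str) -> tuple[float, bool]:
    text = text.strip()
    if text.startswith(">"):
        return CAP_MINUTES, True
    value = float(text)
    if value > CAP_MINUTES:
        return CAP_MINUTES, True
    return value, False


def read_entries_csv(path: str | Path, species: str | None = None) -> list[RawEntry]:
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "smiles", "t_half_min"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"CSV must have header columns {sorted(required)}")
        for row in reader:
            t, capped = _parse_t_half(row["t_half_min"])
            entries.append(
                RawEntry(
                    source_id=row["id"],
                    structure=row["smiles"],
                    t_half=t,
                    species=species or row.get("species", "human"),
                    capped=capped,
                )
            )
    return entries


def read_entries_sdf(path: str | Path, species: str | None = None) -> list[RawEntry]:
    entries = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        t, capped = _parse_t_half(mol.GetProp("t_half_min"))
        entries.append(
            RawEntry(
                source_id=mol.GetProp("id") if mol.HasProp("id") else f"sdf-{i}",
                structure=Chem.MolToSmiles(mol),
                t_half=t,
                species=species
                or (mol.GetProp("species") if mol.HasProp("species") else "human"),
                capped=capped,
            )
        )
    return entries


def write_records_csv(records: Sequence[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["inchikey", "smiles_std", "t_half_min", "capped", "stability_class", "species"]
        )
        for r in records:
            t = ">120" if r.capped else f"{r.t_half:g}"
            writer.writerow(
                [r.inchikey, r.smiles_std, t, int(r.capped), r.stability_class, r.species]
            )


def read_records_csv(path: str | Path) -> list[CompoundRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            t, capped = _parse_t_half(row["t_half_min"])
            records.append(
                CompoundRecord(
                    inchikey=row["inchikey"],
                    smiles_std=row["smiles_std"],
                    t_half=t,
                    capped=capped or bool(int(row.get("capped", 0))),
                    stability_class=row["stability_class"],
                    species=row["species"],
                )
            )
    return records
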