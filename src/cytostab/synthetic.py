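"""Synthetic compound libraries with planted structure–stability relationships.

The generator emulates the structure of a medicinal-chemistry screening
collection: scaffold series share a constant core and vary a single
substituent (matched-molecular-pair structure by construction), half-lives
are log-normal with a structure-linked component (polar compounds drift
stable, lipophilic ones unstable), latent stability rules multiply the
half-life of trigger-bearing compounds by a known fold, measurements carry
multiplicative log-normal noise, and reporting is capped at 120 min. Class
prevalence is calibrated to a target (25% unstable for the human-like
setting, 10% for the mouse-like one) by shifting the log-scale location.

Everything is deterministic per seed, and the planted rule yields a
ground-truth pair/transform list used as the recovery oracle by the MMPA and
QSAR test suites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

from cytostab.halflife import CAP_MINUTES, DEFAULT_TIMES, DepletionTimeCourse, HalfLife, classify_stability
from cytostab.standardize import CompoundRecord, compute_inchikey, standardize_structure

# Aromatic / heteroaromatic cores, one attachment point each.
CORES: tuple[str, ...] = (
    "[*:1]c1ccc(F)cc1",
    "[*:1]c1ccc(Cl)cc1",
    "[*:1]c1ccc(OC)cc1",
    "[*:1]c1ccc(C)cc1",
    "[*:1]c1ccc(C(F)(F)F)cc1",
    "[*:1]c1ccccc1F",
    "[*:1]c1cccc(F)c1",
    "[*:1]c1ccncc1",
    "[*:1]c1ccc2ccccc2c1",
    "[*:1]c1ccc(cc1)N1CCOCC1",
    "[*:1]c1ccc(cc1)S(C)(=O)=O",
    "[*:1]c1ccc(cc1)C#N",
    "[*:1]c1ccc(cc1)N(C)C",
    "[*:1]c1ccsc1",
    "[*:1]c1ccco1",
    "[*:1]c1cnn(C)c1",
    "[*:1]c1ncccn1",
    "[*:1]c1nc2ccccc2s1",
    "[*:1]c1ccc(cc1)-c1ccccc1",
    "[*:1]c1cccc(OC)c1",
    "[*:1]c1ccc(Br)cc1",
    "[*:1]c1ccc(CC)cc1",
    "[*:1]c1ccc(OCC)cc1",
    "[*:1]c1ccccc1Cl",
    "[*:1]c1cccc(Cl)c1",
    "[*:1]c1ccccc1C",
    "[*:1]c1cccc(C)c1",
    "[*:1]c1ccccc1OC",
    "[*:1]c1cnccn1",
    "[*:1]c1cccnc1",
    "[*:1]c1ccccn1",
    "[*:1]c1ccc2occc2c1",
    "[*:1]c1ccc(cc1)N1CCCC1",
    "[*:1]c1ccc(cc1)C(C)C",
    "[*:1]c1ccc(cc1)SC",
    "[*:1]c1csc(C)c1",
    "[*:1]c1coc(C)c1",
    "[*:1]c1cnn(CC)c1",
    "[*:1]c1ccc(cc1)C1CC1",
    "[*:1]c1ccc2ncccc2c1",
)

# Common R-group vocabulary; every entry assembles into a valid molecule
# with every core above.
SUBSTITUENTS: tuple[str, ...] = (
    "[*:1]C",
    "[*:1]CC",
    "[*:1]CCC",
    "[*:1]C(C)C",
    "[*:1]CCCC",
    "[*:1]C(C)(C)C",
    "[*:1]OC",
    "[*:1]OCC",
    "[*:1]OC(C)C",
    "[*:1]O",
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]Br",
    "[*:1]C#N",
    "[*:1]C(F)(F)F",
    "[*:1]OC(F)(F)F",
    "[*:1]N",
    "[*:1]NC",
    "[*:1]N(C)C",
    "[*:1]NC(C)=O",
    "[*:1]C(=O)NC",
    "[*:1]C(N)=O",
    "[*:1]C=O",
    "[*:1]C(C)=O",
    "[*:1]C(=O)OC",
    "[*:1]C(=O)O",
    "[*:1]S(C)(=O)=O",
    "[*:1]SC",
    "[*:1]CO",
    "[*:1]CCO",
    "[*:1]CN",
    "[*:1]CN(C)C",
    "[*:1]CC#N",
    "[*:1]COC",
    "[*:1]C1CC1",
    "[*:1]C1CCC1",
    "[*:1]C1CCCC1",
    "[*:1]C1CCOCC1",
    "[*:1]N1CCCC1",
    "[*:1]N1CCOCC1",
    "[*:1]N1CCN(C)CC1",
    "[*:1]c1ccccc1",
    "[*:1]Cc1ccccc1",
    "[*:1]CF",
    "[*:1]CC(F)(F)F",
    "[*:1]OCCOC",
    "[*:1]CNC(C)=O",
    "[*:1]CCN1CCOCC1",
)


@dataclass(frozen=True)
class StabilityRule:
    """A latent rule: trigger-bearing compounds get t½ × effect."""

    trigger: str  # SMARTS
    effect: float  # multiplicative fold on t½ (> 1 stabilizing)
    species_scope: str = "both"  # human | mouse | both

    def __post_init__(self):
        if self.effect <= 0:
            raise ValueError("rule effect must be positive")
        if Chem.MolFromSmarts(self.trigger) is None:
            raise ValueError(f"invalid trigger SMARTS {self.trigger!r}")


# Default planted chemistry: the aryl aldehyde handle (a classic aldehyde
# oxidase substrate) destabilizes 4-fold; swapping it for a primary amide
# removes the liability, so the aldehyde → amide transform is the planted
# stability-enhancing rule (expected fold 4).
DEFAULT_SWAP = ("[*:1]C=O", "[*:1]C(N)=O")
DEFAULT_RULES = (StabilityRule(trigger="[cX3][CX3H1]=[OX1]", effect=0.25),)


@dataclass
class SimConfig:
    """Study conditions for the synthetic library."""

    n_series: int = 24
    series_size_range: tuple[int, int] = (20, 40)
    baseline_log_mu: float = math.log(55.0)  # minutes, log-normal location
    baseline_log_sigma: float = 0.9  # log-normal scale
    structure_frac: float = 0.9  # fraction of baseline variance that is structural
    rules: tuple[StabilityRule, ...] = DEFAULT_RULES
    planted_swap: tuple[str, str] = DEFAULT_SWAP
    target_unstable_prevalence: float = 0.25
    noise_cv: float = 0.10  # measurement CV on t½
    cap: float = CAP_MINUTES
    species: str = "human"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_unstable_prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.structure_frac <= 1:
            raise ValueError("structure_frac must be in [0, 1]")


def _canon_frag(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


def assemble(core: str, substituent: str) -> str:
    """Join a core and a substituent at their mapped attachment points."""
    mol = Chem.molzip(Chem.MolFromSmiles(core), Chem.MolFromSmiles(substituent))
    Chem.SanitizeMol(mol)
    return standardize_structure(Chem.MolToSmiles(mol))


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_library(
    cfg: SimConfig,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Assemble scaffold series and draw half-lives with planted structure.

    Returns deduplicated records (measured, capped half-lives and classes)
    plus a truth table with one row per compound: series, core, substituent,
    structural score, true and measured half-life.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.series_size_range
    if lo < 2 or hi < lo:
        raise ValueError("invalid series_size_range")
    forced = [s for s in cfg.planted_swap if cfg.rules] if cfg.rules else []
    pool = [s for s in SUBSTITUENTS if s not in forced]

    rows = []
    seen: set[str] = set()
    for s in range(cfg.n_series):
        core = CORES[s % len(CORES)]
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(forced) + len(pool))
        picked = rng.choice(len(pool), size=size - len(forced), replace=False)
        subs = forced + [pool[i] for i in sorted(picked)]
        for sub in subs:
            smi = assemble(core, sub)
            key = compute_inchikey(smi)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {"series": s, "core": core, "substituent": sub, "smiles": smi, "inchikey": key}
            )
    truth = pd.DataFrame(rows)
    n = len(truth)

    # Structure-linked log-half-life component: polarity stabilizes,
    # lipophilicity destabilizes.
    logp = np.empty(n)
    tpsa = np.empty(n)
    for i, smi in enumerate(truth["smiles"]):
        mol = Chem.MolFromSmiles(smi)
        logp[i] = Crippen.MolLogP(mol)
        tpsa[i] = rdMolDescriptors.CalcTPSA(mol)
    combo = (tpsa - tpsa.mean()) / tpsa.std() - (logp - logp.mean()) / logp.std()
    z_struct = (combo - combo.mean()) / combo.std()
    struct = cfg.baseline_log_sigma * math.sqrt(cfg.structure_frac) * z_struct
    eps = rng.normal(
        0.0, cfg.baseline_log_sigma * math.sqrt(1.0 - cfg.structure_frac), size=n
    )

    rule_log = np.zeros(n)
    applicable = [
        r for r in cfg.rules if r.species_scope in ("both", cfg.species)
    ]
    patterns = [(Chem.MolFromSmarts(r.trigger), math.log(r.effect)) for r in applicable]
    for i, smi in enumerate(truth["smiles"]):
        mol = Chem.MolFromSmiles(smi)
        for patt, log_effect in patterns:
            if mol.HasSubstructMatch(patt):
                rule_log[i] += log_effect

    meas_noise = rng.normal(0.0, _lognormal_sigma(cfg.noise_cv), size=n)
    s_measured = struct + eps + rule_log + meas_noise

    # Calibrate the log-scale location so the realized unstable fraction hits
    # the target; the 120 min cap does not disturb the ≤30 min count.
    mu0 = math.log(30.0) - float(
        np.quantile(s_measured, cfg.target_unstable_prevalence)
    )
    median_t = math.exp(mu0 + float(np.median(s_measured)))
    if not 0.05 <= median_t <= 1e5:
        raise ValueError(
            f"prevalence target infeasible: calibrated median t1/2 {median_t:.3g} min"
        )

    truth["true_t_half"] = np.exp(mu0 + struct + eps + rule_log)
    truth["measured_t_half"] = np.exp(mu0 + s_measured)
    records = []
    for i, row in truth.iterrows():
        t = float(row["measured_t_half"])
        capped = t > cfg.cap
        h = HalfLife(cfg.cap if capped else t, capped)
        records.append(
            CompoundRecord(
                inchikey=row["inchikey"],
                smiles_std=row["smiles"],
                t_half=h.value,
                capped=h.capped,
                stability_class=classify_stability(h),
                species=cfg.species,
                source_id=f"syn-{cfg.seed}-{i}",
            )
        )
    return records, truth


def generate_timecourse(
    t_half: float, noise_cv: float, seed: int, times: Sequence[float] = DEFAULT_TIMES
) -> DepletionTimeCourse:
    """Noisy first-order depletion course: 100·2^(−t/t½) × log-normal noise.

    Noise applies at t = 0 as well (the assay's t = 0 read is a measurement
    like any other). Deterministic per seed.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    clean = 100.0 * np.power(2.0, -t / t_half)
    noise = np.exp(rng.normal(0.0, _lognormal_sigma(noise_cv), size=len(t)))
    return DepletionTimeCourse(times=tuple(t), remaining=tuple(clean * noise))


def plant_matched_pairs(
    cfg: SimConfig,
) -> tuple[list[CompoundRecord], pd.DataFrame, tuple[str, str]]:
    """Generate a library plus its ground-truth planted-pair list.

    The rule-bearing substituent is whichever side of ``cfg.planted_swap``
    triggers a rule once assembled. Ground-truth pairs are oriented in the
    stability-enhancing direction: out of the rule-bearing analogue when the
    rule destabilizes (effect < 1, expected fold 1/effect), into it when the
    rule stabilizes (expected fold = effect). Every other compound of a
    series containing the bearer forms one directional pair with it.
    Returns ``(records, ground_truth, planted_transform)`` where the
    transform is the canonical (lhs_frag, rhs_frag) of the designated swap
    in the same stability-enhancing direction.
    """
    if not cfg.rules:
        records, truth = generate_library(cfg)
        return records, pd.DataFrame(
            columns=["left_inchikey", "right_inchikey", "series", "expected_fold"]
        ), ("", "")
    records, truth = generate_library(cfg)
    by_key = {r.inchikey: r for r in records}

    applicable = [r for r in cfg.rules if r.species_scope in ("both", cfg.species)]
    patterns = [Chem.MolFromSmarts(r.trigger) for r in applicable]

    def _rule_effect(sub: str) -> float:
        probe = Chem.MolFromSmiles(assemble(CORES[0], sub))
        return float(
            np.prod(
                [
                    r.effect
                    for r, p in zip(applicable, patterns)
                    if probe.HasSubstructMatch(p)
                ]
            )
        )

    effects = {sub: _rule_effect(sub) for sub in cfg.planted_swap}
    bearer_sub = min(cfg.planted_swap, key=lambda s: abs(math.log(effects[s])) * -1)
    effect = effects[bearer_sub]
    if effect == 1.0:
        raise ValueError("no rule triggers on either planted-swap substituent")
    bearer_is_left = effect < 1.0
    expected_fold = 1.0 / effect if bearer_is_left else effect

    gt_rows = []
    for series, group in truth.groupby("series"):
        bearer = group[group["substituent"] == bearer_sub]
        if bearer.empty:
            continue
        bearer_key = bearer.iloc[0]["inchikey"]
        for _, row in group.iterrows():
            if row["inchikey"] == bearer_key:
                continue
            left_key, right_key = (
                (bearer_key, row["inchikey"])
                if bearer_is_left
                else (row["inchikey"], bearer_key)
            )
            gt_rows.append(
                {
                    "left_inchikey": left_key,
                    "right_inchikey": right_key,
                    "series": series,
                    "partner_substituent": row["substituent"],
                    "expected_fold": expected_fold,
                }
            )
    partner_sub = [s for s in cfg.planted_swap if s != bearer_sub][0]
    if bearer_is_left:
        transform = (_canon_frag(bearer_sub), _canon_frag(partner_sub))
    else:
        transform = (_canon_frag(partner_sub), _canon_frag(bearer_sub))
    # keep only pairs whose members survived dedup
    gt = pd.DataFrame(gt_rows)
    if not gt.empty:
        gt = gt[
            gt["left_inchikey"].isin(by_key) & gt["right_inchikey"].isin(by_key)
        ].reset_index(drop=True)
    return records, gt, transform
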