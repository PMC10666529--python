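"""Synthetic snapshot series with known ground-truth transformations.

The generator emulates a sunlight photodegradation time series of a complex
mixture: a pool of CHNOS formulas with log-uniform initial intensities
reacts along a configurable subset of transformation units with first-order
kinetics.  Per transition t with dose d_t, each formula's competing feasible
reactions (rate constants k_u) remove the fraction 1 - exp(-d_t * sum k_u)
of its intensity, split across the reactions proportionally to k_u; every
transfer is recorded as ground truth.  Multiplicative log-normal noise is
applied to the observed tables only, because the TPA margin acts on
intensity ratios.

This is a test fixture, not a chemical claim: real DOM has orders of
magnitude more formulas, mass-dependent reactivity, and intensity changes
that are not mass-conserving.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formulas import ElementVector, MolecularFormula
from .units import UnitTable, apply_unit, default_units

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulationResult",
    "simulate",
    "RecoveryResult",
    "evaluate_recovery",
]

#: Dose pattern over 12 transitions mimicking a multi-day sunlight experiment:
#: mornings ramp up, middays peak, one overnight transition has zero dose, and
#: the final days carry the largest cumulative doses.
DEFAULT_DOSES = (0.3, 0.5, 1.0, 0.8, 0.0, 0.4, 0.6, 1.2, 0.9, 0.5, 1.5, 1.8)

#: First-order rate constants (per unit dose) for the photochemically dominant
#: units: decarboxylation and dehydration fast, oxidations intermediate,
#: heteroatom losses and nitration slow.
DEFAULT_RATES = {
    "-CO2": 0.20,
    "-H2O": 0.15,
    "+O": 0.12,
    "-H2+O": 0.08,
    "-SO3": 0.05,
    "+NO2-H": 0.04,
}


@dataclass
class SimulationConfig:
    """World description for the simulator; defaults emulate a 13-time-point
    natural-sunlight photolysis series."""

    n_formulas: int = 300
    n_snapshots: int = 13
    c_range: tuple[int, int] = (6, 30)
    hc_range: tuple[float, float] = (0.6, 1.8)
    oc_range: tuple[float, float] = (0.1, 0.8)
    p_nitrogen: float = 0.25  #: probability a seed formula carries N (1-2 atoms)
    p_sulfur: float = 0.12  #: probability of one S atom
    intensity_range: tuple[float, float] = (1e-3, 1.0)  #: log-uniform initial intensities
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    doses: Optional[tuple[float, ...]] = None  #: per-transition; default pattern
    noise_sigma: float = 0.05  #: log-normal sigma, matches the 5% error margin scale
    mineralization_rate: float = 0.0  #: first-order loss to an unobserved sink
    #: reaction-chain depth: seeds are generation 0 and a formula reacts only
    #: while its generation is < max_chain, keeping the formula universe
    #: bounded (an unbounded cascade grows exponentially with transitions)
    max_chain: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_snapshots < 2:
            raise ValueError("need at least 2 snapshots")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(k < 0 for k in self.rates.values()) or self.mineralization_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.max_chain < 1:
            raise ValueError("max_chain must be >= 1")
        if self.doses is None:
            n_trans = self.n_snapshots - 1
            reps = -(-n_trans // len(DEFAULT_DOSES))
            self.doses = (DEFAULT_DOSES * reps)[:n_trans]
        if len(self.doses) != self.n_snapshots - 1:
            raise ValueError(
                f"need {self.n_snapshots - 1} doses, got {len(self.doses)}"
            )


@dataclass(frozen=True, order=True)
class TruthRecord:
    """One actual intensity transfer: educt -> product via unit on transition."""

    educt: str
    product: str
    unit: str
    transition: int
    amount: float


@dataclass
class SimulationResult:
    observed: dict[int, dict[str, float]]  #: noisy peak tables
    true_intensities: dict[int, dict[str, float]]  #: noise-free ledger
    truth: list[TruthRecord]
    config: SimulationConfig


def _sample_formulas(cfg: SimulationConfig, rng: np.random.Generator) -> list[MolecularFormula]:
    seen: set[str] = set()
    out: list[MolecularFormula] = []
    attempts = 0
    while len(out) < cfg.n_formulas and attempts < cfg.n_formulas * 50:
        attempts += 1
        c = int(rng.integers(cfg.c_range[0], cfg.c_range[1] + 1))
        h = max(1, round(c * rng.uniform(*cfg.hc_range)))
        o = max(1, round(c * rng.uniform(*cfg.oc_range)))
        n = int(rng.integers(1, 3)) if rng.random() < cfg.p_nitrogen else 0
        s = 1 if rng.random() < cfg.p_sulfur else 0
        mf = MolecularFormula.from_elements(ElementVector(c=c, h=h, n=n, o=o, s=s))
        if mf.canonical not in seen:
            seen.add(mf.canonical)
            out.append(mf)
    return out


def simulate(cfg: SimulationConfig, units: Optional[UnitTable] = None) -> SimulationResult:
    """Run the kinetic simulation; deterministic for a fixed config/seed.

    Emits a warning (but still returns tables) when no reaction is feasible
    for any seed formula, e.g. under an overly restrictive unit subset.
    """
    units = units or default_units()
    active = [(units[name], k) for name, k in cfg.rates.items() if name in units and k > 0]
    rng = np.random.default_rng(cfg.seed)

    pool = _sample_formulas(cfg, rng)
    lo, hi = cfg.intensity_range
    intens = {
        mf.canonical: float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        for mf in pool
    }
    parsed = {mf.canonical: mf for mf in pool}

    true_tabs: dict[int, dict[str, float]] = {1: dict(intens)}
    truth: list[TruthRecord] = []
    any_feasible = False
    generation = {f: 0 for f in intens}

    feasible_cache: dict[str, list] = {}

    def feasible_reactions(formula: str) -> list:
        if formula not in feasible_cache:
            mf = parsed.get(formula)
            if mf is None:
                from .formulas import parse_formula

                mf = parsed[formula] = parse_formula(formula)
            feats = []
            for unit, k in active:
                prod = apply_unit(mf, unit)
                if prod is not None and prod.canonical != formula:
                    feats.append((unit, k, prod.canonical))
            feasible_cache[formula] = feats
        return feasible_cache[formula]

    current = dict(intens)
    for t in range(1, cfg.n_snapshots):
        dose = cfg.doses[t - 1]
        nxt = dict(current)
        for formula, inten in current.items():
            if inten <= 0 or generation.get(formula, 0) >= cfg.max_chain:
                continue
            feats = feasible_reactions(formula)
            k_min = cfg.mineralization_rate
            k_tot = sum(k for _, k, _ in feats) + k_min
            if not feats and k_min == 0:
                continue
            any_feasible = any_feasible or bool(feats)
            outflow = inten * (1.0 - math.exp(-dose * k_tot)) if k_tot > 0 else 0.0
            if outflow <= 0:
                continue
            nxt[formula] -= outflow
            gen_next = generation.get(formula, 0) + 1
            for unit, k, prod_name in feats:
                amount = outflow * k / k_tot
                nxt[prod_name] = nxt.get(prod_name, 0.0) + amount
                if prod_name not in generation or generation[prod_name] > gen_next:
                    generation[prod_name] = gen_next
                truth.append(
                    TruthRecord(educt=formula, product=prod_name, unit=unit.name,
                                transition=t, amount=amount)
                )
            # mineralized share (outflow * k_min / k_tot) leaves the system
        current = {f: i for f, i in nxt.items() if i > 0}
        true_tabs[t + 1] = dict(current)

    if not any_feasible:
        import warnings

        warnings.warn("no feasible reactions under this configuration", stacklevel=2)

    observed: dict[int, dict[str, float]] = {}
    for t, table in true_tabs.items():
        obs = {}
        for formula in sorted(table):
            noise = math.exp(cfg.noise_sigma * rng.standard_normal()) if cfg.noise_sigma else 1.0
            obs[formula] = table[formula] * noise
        observed[t] = obs

    return SimulationResult(
        observed=observed, true_intensities=true_tabs,
        truth=sorted(truth), config=cfg,
    )


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    per_transition: "object"  #: pandas DataFrame transition x (tp, fp, fn, precision, recall)
    true_positives: list[tuple[str, str, int, str]]
    false_positives: list[tuple[str, str, int, str]]
    false_negatives: list[tuple[str, str, int, str]]


def evaluate_recovery(
    predicted: list[tuple[str, str, int, str]], truth: list[TruthRecord]
) -> RecoveryResult:
    """Precision/recall of predicted edges against ground-truth transfers.

    Matching is exact on (educt, product, transition, unit).  With no
    predictions precision is defined as 1.0; with no truth, recall is 1.0.
    """
    import pandas as pd

    pred_set = {(p[0], p[1], p[2], p[3]) for p in predicted}
    truth_set = {(r.educt, r.product, r.transition, r.unit) for r in truth}
    tp = pred_set & truth_set
    fp = pred_set - truth_set
    fn = truth_set - pred_set

    transitions = sorted({k[2] for k in pred_set | truth_set})
    rows = []
    for t in transitions:
        tp_t = sum(1 for k in tp if k[2] == t)
        fp_t = sum(1 for k in fp if k[2] == t)
        fn_t = sum(1 for k in fn if k[2] == t)
        rows.append(
            {
                "transition": t, "tp": tp_t, "fp": fp_t, "fn": fn_t,
                "precision": tp_t / (tp_t + fp_t) if tp_t + fp_t else 1.0,
                "recall": tp_t / (tp_t + fn_t) if tp_t + fn_t else 1.0,
            }
        )
    per_t = pd.DataFrame(rows, columns=["transition", "tp", "fp", "fn", "precision", "recall"])
    if not per_t.empty:
        per_t = per_t.set_index("transition")
    return RecoveryResult(
        precision=len(tp) / len(pred_set) if pred_set else 1.0,
        recall=len(tp) / len(truth_set) if truth_set else 1.0,
        per_transition=per_t,
        true_positives=sorted(tp),
        false_positives=sorted(fp),
        false_negatives=sorted(fn),
    )
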