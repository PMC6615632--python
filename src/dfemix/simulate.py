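"""Synthetic recombinant-line data with the statistical structure the
inference assumes.

The generator emulates a mutation-accumulation backcross: haploid 0/1
genotypes at ``n_m`` mutation sites transmitted independently with
probability ~0.5, mutation effects drawn from a point-mass-category or
two-sided gamma DFE, optional two-level fixed effects and normally
distributed plate effects, and Gaussian residual noise.  Effects are in
residual-standard-deviation units (``V_e`` defaults to 1), which for the
small-effect scenarios is close to phenotypic-SD units.

``VALIDATION_SCENARIOS`` holds the four parameter-recovery settings used to
check the samplers (two-, three- and four-category point-mass DFEs and a
two-sided gamma DFE, each with 40 mutations and 10,000 observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import RLDataset

__all__ = [
    "DFESpec",
    "SimScenario",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_rl_dataset",
    "simulate_growth_curves",
    "make_validation_dataset",
    "VALIDATION_SCENARIOS",
]


@dataclass
class DFESpec:
    """Specification of a distribution of fitness effects.

    ``model`` is ``"multicategory"`` (point masses ``effects`` with
    frequencies ``frequencies``; category 0 must have effect 0) or
    ``"two_sided_gamma"`` (gamma-distributed magnitudes on each side of zero;
    means are magnitudes, the sign is applied by side).
    """

    model: str
    effects: tuple[float, ...] | None = None
    frequencies: tuple[float, ...] | None = None
    mean_neg: float | None = None
    mean_pos: float | None = None
    shape_neg: float | None = None
    shape_pos: float | None = None
    q_pos: float | None = None

    def __post_init__(self) -> None:
        if self.model == "multicategory":
            if self.effects is None or self.frequencies is None:
                raise ValueError("multicategory DFE needs effects and frequencies")
            e = np.asarray(self.effects, dtype=float)
            q = np.asarray(self.frequencies, dtype=float)
            if e.shape != q.shape:
                raise ValueError("effects and frequencies must have equal length")
            if e[0] != 0.0:
                raise ValueError("category 0 is the zero-effect class (e_0 = 0)")
            if (q < 0).any() or (q > 1).any() or not np.isclose(q.sum(), 1.0):
                raise ValueError("frequencies must lie in [0,1] and sum to 1")
        elif self.model == "two_sided_gamma":
            for name in ("mean_neg", "mean_pos", "shape_neg", "shape_pos", "q_pos"):
                if getattr(self, name) is None:
                    raise ValueError(f"two_sided_gamma DFE needs {name}")
            if self.mean_neg < 0 or self.mean_pos < 0:
                raise ValueError("gamma means are magnitudes and must be >= 0")
            if self.shape_neg <= 0 or self.shape_pos <= 0:
                raise ValueError("gamma shapes must be > 0")
            if not 0.0 <= self.q_pos <= 1.0:
                raise ValueError("q_pos must lie in [0,1]")
        else:
            raise ValueError(f"unknown DFE model {self.model!r}")

    @property
    def n_categories(self) -> int:
        if self.model != "multicategory":
            raise AttributeError("n_categories is defined for multicategory DFEs")
        return len(self.effects)


@dataclass
class SimScenario:
    """Dimensions and nuisance structure of a simulated RL experiment.

    Defaults follow the samplers' validation design: 40 mutations, 10,000
    observations, 50% transmission, unit residual variance, and no fixed or
    plate effects (the validation simulations do not state any; both can be
    switched on here).
    """

    n_m: int = 40
    n_b: int = 10_000
    n_f: int = 0
    n_p: int = 0
    V_p: float = 0.0
    V_e: float = 1.0
    ybar: float = 0.0
    transmission_prob: float = 0.5
    fixed_effect_sizes: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_m, self.n_b, self.n_f, self.n_p) < 0:
            raise ValueError("counts must be >= 0")
        if self.V_p < 0 or self.V_e < 0:
            raise ValueError("variances must be >= 0")
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ValueError("transmission_prob must lie in [0,1]")
        if self.fixed_effect_sizes is not None and len(self.fixed_effect_sizes) != self.n_f:
            raise ValueError("fixed_effect_sizes length must equal n_f")


#: Parameter-recovery validation scenarios (40 mutations, 10,000 observations
#: each).  Effects/means in residual-SD units.
VALIDATION_SCENARIOS: dict[str, DFESpec] = {
    "two_category": DFESpec(
        "multicategory", effects=(0.0, 0.25), frequencies=(0.8, 0.2)
    ),
    "three_category": DFESpec(
        "multicategory", effects=(0.0, -0.3, 0.2), frequencies=(0.7, 0.1, 0.2)
    ),
    "four_category": DFESpec(
        "multicategory",
        effects=(0.0, 0.4, 0.2, -0.3),
        frequencies=(0.55, 0.15, 0.2, 0.1),
    ),
    "two_sided_gamma": DFESpec(
        "two_sided_gamma",
        mean_neg=0.5,
        mean_pos=0.25,
        shape_neg=0.5,
        shape_pos=2.0,
        q_pos=0.25,
    ),
}


def simulate_genotypes(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the ``n_b x n_m`` 0/1 genotype matrix.

    Each entry is independently 1 with probability ``transmission_prob``
    (free recombination between mutation sites).
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    return (
        rng.random((scenario.n_b, scenario.n_m)) < scenario.transmission_prob
    ).astype(np.int8)


def _stratified_labels(
    probs: np.ndarray, n_m: int, rng: np.random.Generator
) -> np.ndarray:
    """Label assignment with counts fixed at their expectations (rounded),
    in shuffled order.  Used by the recovery-validation harness so the DFE
    embodied in the data matches the nominal one instead of carrying
    multinomial composition noise (relevant at n_m ~ 40)."""
    counts = np.floor(probs * n_m).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = probs * n_m - counts
    for k in np.argsort(-frac)[: n_m - counts.sum()]:
        counts[k] += 1
    labels = np.repeat(np.arange(len(probs)), counts)
    rng.shuffle(labels)
    return labels.astype(np.int64)


def simulate_effects(
    dfe: DFESpec,
    n_m: int,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-mutation signed effects and category/side labels.

    For multicategory DFEs labels index the categories and the effect is the
    category point mass.  For two-sided gamma DFEs the label is the side
    (0 negative, 1 positive), the magnitude is gamma with that side's mean and
    shape, and the sign is applied by side.  With ``stratified=True`` label
    counts are fixed at their expected values instead of drawn at random.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if dfe.model == "multicategory":
        probs = np.asarray(dfe.frequencies, dtype=float)
        if stratified:
            labels = _stratified_labels(probs, n_m, rng)
        else:
            labels = rng.choice(dfe.n_categories, size=n_m, p=probs)
        effects = np.asarray(dfe.effects, dtype=float)[labels]
        return effects, labels
    if stratified:
        sides = _stratified_labels(
            np.array([1.0 - dfe.q_pos, dfe.q_pos]), n_m, rng
        )
    else:
        sides = (rng.random(n_m) < dfe.q_pos).astype(np.int64)
    mags = np.empty(n_m)
    for side, mean, shape in (
        (0, dfe.mean_neg, dfe.shape_neg),
        (1, dfe.mean_pos, dfe.shape_pos),
    ):
        sel = sides == side
        # gamma with mean m and shape b has scale m/b
        mags[sel] = rng.gamma(shape, mean / shape, size=int(sel.sum()))
    effects = np.where(sides == 1, mags, -mags)
    return effects, sides


def simulate_phenotypes(
    M: np.ndarray,
    effects: np.ndarray,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> RLDataset:
    """Assemble phenotypes y = ybar + g + F f + plate + residual.

    ``g`` is the genotypic value (sum of carried-mutation effects), plate
    effects are Normal(0, V_p), residuals Normal(0, V_e).
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    M = np.asarray(M, dtype=np.int8)
    n_b = M.shape[0]
    if M.shape[1] != len(effects):
        raise ValueError("effects length does not match M columns")
    g = M @ np.asarray(effects, dtype=float)
    y = scenario.ybar + g
    if scenario.n_f:
        F = (rng.random((n_b, scenario.n_f)) < 0.5).astype(np.int8)
        fvals = (
            np.asarray(scenario.fixed_effect_sizes, dtype=float)
            if scenario.fixed_effect_sizes is not None
            else np.zeros(scenario.n_f)
        )
        y = y + F @ fvals
    else:
        F = None
    if scenario.n_p:
        plate = np.arange(n_b) % scenario.n_p
        p_eff = rng.normal(0.0, np.sqrt(scenario.V_p), size=scenario.n_p)
        y = y + p_eff[plate]
    else:
        plate = None
    y = y + rng.normal(0.0, np.sqrt(scenario.V_e), size=n_b)
    return RLDataset(y=y, M=M, F=F, plate=plate)


def simulate_rl_dataset(
    dfe: DFESpec, scenario: SimScenario, stratified: bool = False
) -> tuple[RLDataset, dict]:
    """One-call generator: genotypes, effects and phenotypes from one seed.

    Returns the dataset plus a truth dict (effects, labels, scenario fields)
    suitable for recovery checks and for the JSON sidecar.  ``stratified``
    fixes category/side counts at their expectations (the recovery-
    validation setting).
    """
    rng = np.random.default_rng(scenario.seed)
    M = simulate_genotypes(scenario, rng)
    effects, labels = simulate_effects(dfe, scenario.n_m, rng, stratified=stratified)
    data = simulate_phenotypes(M, effects, scenario, rng)
    truth = {
        "dfe_model": dfe.model,
        "effects": effects,
        "labels": labels,
        "seed": scenario.seed,
        "V_e": scenario.V_e,
        "V_p": scenario.V_p,
    }
    return data, truth


def make_validation_dataset(
    scenario_name: str, seed: int = 0, n_m: int = 40, n_b: int = 10_000
) -> tuple[RLDataset, dict]:
    """Standard parameter-recovery dataset for one validation scenario.

    40 mutations, 10,000 observations, unit residual variance, category/side
    counts fixed at their expected proportions (see ``simulate_effects``)
    so recovery is judged against the nominal DFE.
    """
    dfe = VALIDATION_SCENARIOS[scenario_name]
    sc = SimScenario(n_m=n_m, n_b=n_b, seed=seed)
    return simulate_rl_dataset(dfe, sc, stratified=True)


def simulate_growth_curves(
    true_rates,
    n_replicates: int = 1,
    wells_per_plate: int = 58,
    t_start: float = 12.0,
    t_end: float = 96.0,
    dt: float = 12.0,
    a0: float = 0.005,
    carrying_capacity: float | None = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate logistic growth curves read every 12 h over 12-96 h.

    Returns a long-format table (plate, well, line, replicate, time_h, od650)
    matching the growth-rate module's CSV contract.  Absorbance follows a
    logistic curve A(t) = K a0 e^{rt} / (K + a0 (e^{rt} - 1)) (pure
    exponential when ``carrying_capacity`` is None) with optional
    multiplicative log-normal noise; for small ``a0`` the maximum slope of
    ln A over the candidate windows equals the true rate up to that noise.
    """
    rates = np.asarray(true_rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("growth rates must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    t = np.arange(t_start, t_end + 0.5 * dt, dt)
    rows = []
    for rep in range(n_replicates):
        for i, r in enumerate(rates):
            plate = i // wells_per_plate
            if carrying_capacity is None:
                A = a0 * np.exp(r * t)
            else:
                K = carrying_capacity
                ert = np.exp(r * t)
                A = K * a0 * ert / (K + a0 * (ert - 1.0))
            if noise_sd > 0:
                A = A * np.exp(rng.normal(0.0, noise_sd, size=t.shape))
            for tj, aj in zip(t, A):
                rows.append(
                    {
                        "plate": plate,
                        "well": i % wells_per_plate,
                        "line": f"RL{i:04d}",
                        "replicate": rep,
                        "time_h": tj,
                        "od650": aj,
                    }
                )
    return pd.DataFrame(rows)
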