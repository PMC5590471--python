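"""Simulation harnesses: detection rates, bias validation, resolver study.

Three experiments mirror the evaluation protocol of the misspecification
toolkit on random networks:

* ``run_detection_experiment`` -- per replicate, generate a fresh network and
  noisy data, remove reactions, and record rejections.  True positives come
  from testing the reduced model (with the truth Z for the F/LM tests); false
  positives from the RESET test on the full model, or from the F/LM tests on
  the reduced model with a decoy Z of the same size.  TP+FN = 1 and FP+TN = 1
  by construction.
* ``run_bias_experiment`` -- closed-form specification bias for single-reaction
  removals, checked against the mean ANOVA p value of misspecified fits.
* ``run_resolver_experiment`` -- the nested model x data loop of the repair
  study: remove ``n_extra`` reactions to form the true network, remove
  ``n_omit`` more to form the fitted one, pool all removals as candidates,
  resolve, and count what was never promoted, split by provenance.

Tests are applied to the raw (unwhitened) OLS problem by default: with
CoV-scaled noise the data are heteroscedastic, which is precisely the regime
in which the RESET test collapses; a whitened mode is available via
``whiten=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fluxreg import RegressionProblem, gls_fit, regression_anova
from .misspec import (DEFAULT_ALPHA, CandidateBlock, TestResult, f_test,
                      lm_test, reset_test, specification_bias)
from .netgen import (ExchangeBlocks, NetworkSpec, make_misspecified,
                     noise_free_measurements, random_stoichiometry,
                     sample_internal_fluxes, simulate_dataset,
                     simulate_measurements)
from .resolver import ResolveConfig, resolve, summarize_resolution
from .stoichio import MetabolicModel

DEFAULT_REPS = 200


@dataclass(frozen=True)
class SimScenario:
    """One cell of the detection-rate experiment grid."""

    m: int
    n_internal: int
    n_exchange: int
    n_omit: int
    cov: float
    replicates: int = DEFAULT_REPS
    seed: int = 0

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(m=self.m, n_internal=self.n_internal,
                           n_exchange=self.n_exchange, seed=self.seed)

    def __post_init__(self):
        if not 0 < self.n_omit < self.n_internal:
            raise ValueError("n_omit must be in (0, n_internal)")
        if self.cov < 0:
            raise ValueError("cov must be nonnegative")


@dataclass
class RateTable:
    """TP/FN/FP/TN rates per test for one scenario.

    Rates are rejection fractions over the replicate count, so the
    complement identities TP + FN = 1 and FP + TN = 1 hold exactly.
    """

    scenario: SimScenario
    rates: dict[str, dict[str, float]]
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for test, r in self.rates.items():
            rows.append({"m": self.scenario.m, "n_internal": self.scenario.n_internal,
                         "n_exchange": self.scenario.n_exchange,
                         "n_omit": self.scenario.n_omit, "cov": self.scenario.cov,
                         "test": test, **r, "replicates": self.replicates})
        return pd.DataFrame(rows)


def _apply_test(test: str, problem: RegressionProblem,
                cand: CandidateBlock | None, alpha: float,
                reset_order: int) -> TestResult:
    if test == "reset":
        return reset_test(problem, order_p=reset_order, alpha=alpha)
    if test == "f":
        return f_test(problem, cand, alpha=alpha)
    if test == "lm":
        return lm_test(problem, cand, alpha=alpha)
    raise ValueError(f"unknown test {test!r}")


def run_detection_experiment(scenario: SimScenario,
                             tests: Sequence[str] = ("f",),
                             reps: int | None = None,
                             seed: int | None = None,
                             alpha: float = DEFAULT_ALPHA,
                             reset_order: int = 1,
                             whiten: bool = False,
                             homoscedastic: bool = False) -> RateTable:
    """Estimate TP/FN/FP/TN rates for the requested tests on one scenario.

    Each replicate uses a fresh random network, flux draw and noise draw.
    The TP arm applies each test to the reduced design (F/LM with the truth
    Z); the FP arm applies the RESET test to the full design and the F/LM
    tests to the reduced design with a decoy Z.
    """
    reps = scenario.replicates if reps is None else reps
    seed = scenario.seed if seed is None else seed
    spec = scenario.network_spec()
    need_decoys = any(t in ("f", "lm") for t in tests)
    rejections = {t: {"tp": 0, "fp": 0} for t in tests}
    rep_seeds = np.random.SeedSequence(seed).spawn(reps)
    for ss in rep_seeds:
        ds = simulate_dataset(spec, scenario.n_omit, scenario.cov, ss,
                              with_decoys=need_decoys,
                              homoscedastic=homoscedastic)
        cov_e = _noise_cov(ds.sd, scenario.m) if whiten else None
        reduced_prob = RegressionProblem(y=ds.y, X=ds.reduced.S, cov_e=cov_e)
        truth_cand = CandidateBlock(Z=ds.omitted.S_O,
                                    reaction_ids=list(ds.omitted.reaction_ids))
        for t in tests:
            if t == "reset":
                full_prob = RegressionProblem(y=ds.y, X=ds.model.S, cov_e=cov_e)
                tp = _apply_test(t, reduced_prob, None, alpha, reset_order)
                fp = _apply_test(t, full_prob, None, alpha, reset_order)
            else:
                tp = _apply_test(t, reduced_prob, truth_cand, alpha, reset_order)
                fp = _apply_test(t, reduced_prob, ds.decoys, alpha, reset_order)
            rejections[t]["tp"] += tp.reject
            rejections[t]["fp"] += fp.reject
    rates = {}
    for t in tests:
        tp = rejections[t]["tp"] / reps
        fp = rejections[t]["fp"] / reps
        rates[t] = {"tp": tp, "fn": 1.0 - tp, "fp": fp, "tn": 1.0 - fp}
    return RateTable(scenario=scenario, rates=rates, replicates=reps, seed=seed)


def _noise_cov(sd: np.ndarray, m: int, floor_factor: float = 1e-6) -> np.ndarray:
    """Diagonal noise covariance for a synthetic dataset, variance-floored.

    Variances below 1e-12 of the largest count as zero and are floored, so a
    near-zero noise-free measurement cannot produce a pathological weight.
    """
    var = np.zeros(m)
    var[:sd.shape[0]] = sd ** 2
    zero = var <= 1e-12 * (var.max() if var.size else 0.0)
    nonzero = var[~zero]
    floor = floor_factor * (nonzero.min() if nonzero.size else 1.0)
    return np.diag(np.where(zero, floor, var))


def run_detection_grid(scenarios: Iterable[SimScenario],
                       tests: Sequence[str] = ("f",),
                       reps: int | None = None, seed: int = 0,
                       **kwargs) -> pd.DataFrame:
    """Run a grid of scenarios with independent seed streams; tidy output."""
    scenarios = list(scenarios)
    streams = np.random.SeedSequence(seed).spawn(len(scenarios))
    frames = []
    for scen, ss in zip(scenarios, streams):
        table = run_detection_experiment(
            scen, tests=tests, reps=reps,
            seed=int(ss.generate_state(1)[0] % (2 ** 31)), **kwargs)
        frames.append(table.to_frame())
    return pd.concat(frames, ignore_index=True)


def run_bias_experiment(model: MetabolicModel, blocks: ExchangeBlocks,
                        v_ref: np.ndarray, omitted_ids: Sequence[str],
                        cov: float, reps: int = 200, seed: int = 0,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Single-reaction-removal bias study on a synthetic network.

    For each listed reaction: the closed-form bias summary (relative to the
    reference fluxes ``v_ref``, in percent, over the remaining fluxes) plus
    the mean ANOVA p value of GLS fits of the reduced model to ``reps``
    independently contaminated data vectors generated from the full model.
    """
    col = {r: j for j, r in enumerate(model.reaction_ids)}
    y_free = noise_free_measurements(v_ref, blocks)
    sd = cov * np.abs(y_free[:blocks.n_exchange])
    cov_e = _noise_cov(sd, model.n_metabolites)
    rows = []
    streams = np.random.SeedSequence(seed).spawn(len(omitted_ids))
    for rid, ss in zip(omitted_ids, streams):
        j = col[rid]
        keep = [i for i in range(model.n_reactions) if i != j]
        S_red = model.S[:, keep]
        ref_remaining = v_ref[keep]
        bias = specification_bias(S_red, model.S[:, [j]], [v_ref[j]],
                                  reference=ref_remaining)
        rng = np.random.default_rng(ss)
        p_values = np.empty(reps)
        for r in range(reps):
            noise = rng.normal(0.0, 1.0, size=sd.shape[0]) * sd
            y = y_free.copy()
            y[:blocks.n_exchange] += noise
            prob = RegressionProblem(y=y, X=S_red, cov_e=cov_e)
            est = gls_fit(prob)
            p_values[r] = regression_anova(est, prob).p_value
        rows.append({
            "reaction_id": rid, "v_ref": v_ref[j],
            "mean_anova_p": float(p_values.mean()),
            "se_anova_p": float(p_values.std(ddof=1) / np.sqrt(reps)),
            "significant": bool(p_values.mean() < alpha),
            **{f"abs_rel_bias_{k}": v for k, v in bias.summary.items()},
        })
    return pd.DataFrame(rows)


@dataclass
class ResolverExperimentResult:
    """Aggregate of the repair study: remaining candidates by provenance.

    ``mean_remaining_*`` is the mean over model replicates of the per-model
    median across data replicates, with the standard error of that mean.
    """

    k_schedule: tuple[int, ...]
    n_extra: int
    n_omit: int
    mean_remaining_extra: float
    se_remaining_extra: float
    mean_remaining_omitted: float
    se_remaining_omitted: float
    model_reps: int
    data_reps: int
    per_model_medians: pd.DataFrame = field(repr=False, default=None)


def run_resolver_experiment(base_spec: NetworkSpec, n_extra: int, n_omit: int,
                            k_schedule: tuple[int, ...] = (1,),
                            cov: float = 0.01,
                            model_reps: int = 10, data_reps: int = 10,
                            alpha: float = DEFAULT_ALPHA,
                            seed: int = 0) -> ResolverExperimentResult:
    """Nested repair study on synthetic networks.

    One base network is generated from ``base_spec``.  Outer loop: remove a
    fresh random set of ``n_extra`` columns from the base to get the
    data-generating network.  Inner loop: draw reference fluxes from its
    null space, contaminate the measurements (CoV-scaled noise), remove
    ``n_omit`` further columns to get the fitted model, pool both removal
    sets as candidates, resolve, and count the candidates never promoted,
    split into truly-omitted versus extra (decoy) reactions.
    """
    root = np.random.SeedSequence(seed)
    base_ss, *outer = root.spawn(1 + model_reps)
    base = random_stoichiometry(base_spec, seed=np.random.default_rng(base_ss))
    med_rows = []
    for mi, ss in enumerate(outer):
        extra_ss, *inner = ss.spawn(1 + data_reps)
        true_model, extra_block = make_misspecified(
            base, np.zeros(base.n_reactions), n_extra,
            seed=np.random.default_rng(extra_ss))
        blocks_true = _reattach(true_model, base_spec.n_exchange)
        extra_ids = set(extra_block.reaction_ids)
        rem_extra, rem_omit = [], []
        for di, dss in enumerate(inner):
            flux_ss, noise_ss, rm_ss = dss.spawn(3)
            v_true = sample_internal_fluxes(blocks_true.S_I_NE,
                                            seed=np.random.default_rng(flux_ss))
            y = simulate_measurements(v_true, blocks_true, cov,
                                      seed=np.random.default_rng(noise_ss))
            reduced, omitted = make_misspecified(
                true_model, v_true, n_omit, seed=np.random.default_rng(rm_ss))
            cand_ids = list(extra_block.reaction_ids) + list(omitted.reaction_ids)
            Z = np.column_stack([extra_block.S_O, omitted.S_O]) \
                if cand_ids else np.empty((base.n_metabolites, 0))
            cand = CandidateBlock(Z=Z, reaction_ids=cand_ids)
            prob = RegressionProblem(y=y, X=reduced.S,
                                     col_labels=list(reduced.reaction_ids))
            state = resolve(prob, cand,
                            ResolveConfig(k_schedule=k_schedule, alpha=alpha))
            summary = summarize_resolution(
                state, truth=(set(omitted.reaction_ids), extra_ids))
            rem_extra.append(summary["remaining_decoys"])
            rem_omit.append(summary["remaining_omitted"])
        med_rows.append({"model": mi,
                         "median_remaining_extra": float(np.median(rem_extra)),
                         "median_remaining_omitted": float(np.median(rem_omit))})
    med = pd.DataFrame(med_rows)
    def _se(x):
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return ResolverExperimentResult(
        k_schedule=tuple(k_schedule), n_extra=n_extra, n_omit=n_omit,
        mean_remaining_extra=float(med["median_remaining_extra"].mean()),
        se_remaining_extra=_se(med["median_remaining_extra"]),
        mean_remaining_omitted=float(med["median_remaining_omitted"].mean()),
        se_remaining_omitted=_se(med["median_remaining_omitted"]),
        model_reps=model_reps, data_reps=data_reps, per_model_medians=med)


def _reattach(model: MetabolicModel, n_exchange: int) -> ExchangeBlocks:
    from .netgen import attach_exchanges
    return attach_exchanges(model, n_exchange)
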