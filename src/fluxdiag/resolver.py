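"""Iterative repair of a misspecified stoichiometric model.

Given a reduced model and a pool of candidate reactions ``S_A``, each
iteration tests every k-tuple of remaining candidates with the nested F test
(or, optionally, the LM test) against the current design, promotes the
passing tuples from the candidate pool into the model, rebuilds the design,
and repeats until an iteration promotes nothing.  The recommended setting is
k = 1 (single reactions); a schedule such as ``[1, 2]`` runs singles to
exhaustion and then pairs.

"Promote the passing combination(s)" is ambiguous when passing tuples
overlap; the default policy promotes greedily in descending-statistic order
within an iteration (skipping tuples that share a member with an
already-promoted tuple or would break full column rank) and then re-tests
everything in the next iteration.  ``promotion="best_only"`` instead promotes
only the top-ranked passing tuple per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .fluxreg import RegressionProblem, ols_fit, whiten_matrix, whiten_problem
from .misspec import DEFAULT_ALPHA, CandidateBlock, f_test, lm_test
from .stoichio import EstimabilityError, check_estimability


@dataclass
class ResolveConfig:
    """Settings for the iterative correction procedure."""

    k_schedule: tuple[int, ...] = (1,)
    alpha: float = DEFAULT_ALPHA
    test: str = "f"  # "f" or "lm"
    promotion: str = "all_passing"  # or "best_only"
    bonferroni: bool = False  # divide alpha by the number of tuples tested
    max_iterations: int = 10_000

    def __post_init__(self):
        if any(k < 1 for k in self.k_schedule):
            raise ValueError("tuple sizes must be >= 1")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.test not in ("f", "lm"):
            raise ValueError("test must be 'f' or 'lm'")
        if self.promotion not in ("all_passing", "best_only"):
            raise ValueError("promotion must be 'all_passing' or 'best_only'")


@dataclass
class IterationRecord:
    """Audit entry for one tested tuple in one iteration."""

    k: int
    iteration: int
    candidate_ids: tuple[str, ...]
    statistic: float
    p_value: float
    passed: bool
    promoted: bool
    note: str = ""


@dataclass
class ResolveState:
    """Result of a resolution run: the repaired design and its audit trail."""

    X_current: np.ndarray
    design_ids: list[str]
    remaining: CandidateBlock
    promoted_ids: list[tuple[str, int, int, float]]  # (id, k, iteration, statistic)
    iteration_log: list[IterationRecord] = field(default_factory=list)

    @property
    def promoted_id_set(self) -> set[str]:
        return {pid for pid, *_ in self.promoted_ids}


def resolve(problem: RegressionProblem, candidates: CandidateBlock,
            config: ResolveConfig = ResolveConfig()) -> ResolveState:
    """Run the iterative F-test (or LM-test) correction procedure.

    The working design starts at the problem's X; candidate columns that pass
    the test are moved into it.  Tuples violating the rank precondition are
    skipped with a logged notice.  Returns the final design, the unpromoted
    candidates, and a complete per-iteration log.

    GLS problems are whitened once up front (the tests are OLS-equivalent on
    the whitened scale), so candidate columns are whitened with the same
    factor.
    """
    if problem.cov_e is not None:
        Z_all = whiten_matrix(problem, candidates.Z)
        problem = whiten_problem(problem)
    else:
        Z_all = np.asarray(candidates.Z, dtype=float)
    pool: dict[str, np.ndarray] = {
        cid: Z_all[:, j] for j, cid in enumerate(candidates.reaction_ids)}
    X = problem.X.copy()
    design_ids = list(problem.col_labels or
                      [f"X{j + 1}" for j in range(X.shape[1])])
    promoted: list[tuple[str, int, int, float]] = []
    log: list[IterationRecord] = []
    test_fn = f_test if config.test == "f" else lm_test
    total_iterations = 0

    for k in config.k_schedule:
        iteration = 0
        while True:
            iteration += 1
            total_iterations += 1
            if total_iterations > config.max_iterations:
                raise RuntimeError(
                    f"exceeded max_iterations={config.max_iterations}; "
                    f"promoted so far: {[p[0] for p in promoted]}")
            remaining_ids = sorted(pool)
            if len(remaining_ids) < k:
                break
            tuples = list(combinations(remaining_ids, k))
            alpha = config.alpha / len(tuples) if config.bonferroni else config.alpha
            current = RegressionProblem(y=problem.y, X=X)
            passing: list[tuple[float, tuple[str, ...]]] = []
            records: dict[tuple[str, ...], IterationRecord] = {}
            for tup in tuples:
                Z = np.column_stack([pool[c] for c in tup])
                cand = CandidateBlock(Z=Z, reaction_ids=list(tup))
                try:
                    res = test_fn(current, cand, alpha=alpha)
                except (EstimabilityError, ValueError) as exc:
                    records[tup] = IterationRecord(
                        k, iteration, tup, np.nan, np.nan, False, False,
                        note=f"skipped: {exc}")
                    continue
                records[tup] = IterationRecord(
                    k, iteration, tup, res.statistic, res.p_value, res.reject,
                    False)
                if res.reject:
                    passing.append((res.statistic, tup))

            # greedy promotion: descending statistic, ties broken by ids
            passing.sort(key=lambda item: (-item[0], item[1]))
            promoted_this_iter: set[str] = set()
            for statistic, tup in passing:
                if promoted_this_iter and config.promotion == "best_only":
                    break
                if promoted_this_iter & set(tup):
                    records[tup].note = "skipped: member already promoted"
                    continue
                trial = np.column_stack([X] + [pool[c] for c in tup])
                if not check_estimability(trial).is_estimable:
                    records[tup].note = "skipped: promotion would break rank"
                    continue
                X = trial
                for c in tup:
                    design_ids.append(c)
                    promoted.append((c, k, iteration, statistic))
                    promoted_this_iter.add(c)
                    del pool[c]
                records[tup].promoted = True
            log.extend(records[t] for t in tuples)
            if not promoted_this_iter:
                break

    remaining_ids = sorted(pool)
    remaining = CandidateBlock(
        Z=(np.column_stack([pool[c] for c in remaining_ids])
           if remaining_ids else np.empty((problem.N, 0))),
        reaction_ids=remaining_ids)
    return ResolveState(X_current=X, design_ids=design_ids,
                        remaining=remaining, promoted_ids=promoted,
                        iteration_log=log)


def summarize_resolution(state: ResolveState,
                         truth: tuple[set[str], set[str]] | None = None) -> dict:
    """Tabulate a resolution run.

    ``truth`` is an optional pair ``(omitted_ids, decoy_ids)``: reactions that
    truly belong in the model versus extras that do not.  Remaining counts of
    each kind measure recovery (low is good for omitted, high for decoys).
    """
    per_iteration: dict[tuple[int, int], int] = {}
    for _, k, iteration, _ in state.promoted_ids:
        per_iteration[(k, iteration)] = per_iteration.get((k, iteration), 0) + 1
    out: dict = {
        "n_promoted": len(state.promoted_ids),
        "n_remaining": state.remaining.n_candidates,
        "promotions_per_iteration": {
            f"k={k},iter={i}": c for (k, i), c in sorted(per_iteration.items())},
        "promoted_ids": [p[0] for p in state.promoted_ids],
        "remaining_ids": list(state.remaining.reaction_ids),
    }
    if truth is not None:
        omitted_ids, decoy_ids = truth
        remaining = set(state.remaining.reaction_ids)
        out["remaining_omitted"] = len(remaining & set(omitted_ids))
        out["remaining_decoys"] = len(remaining & set(decoy_ids))
    return out
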