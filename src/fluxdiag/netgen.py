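"""Random metabolic network generation and in-silico data simulation.

The generator emulates the random-network study design: a random integer
stoichiometric matrix ``S_I`` (m metabolites x n_I internal reactions) with
full column rank in which every species participates in at least one
reaction; exchange fluxes measured on the first ``m_E`` metabolites through
the block exchange matrix ``S_E = [I; 0]``; an internal flux vector drawn
from the null space of the unmeasured-row block ``S_I,NE`` (so the
unmeasured balances close exactly); and measurements contaminated with
zero-mean Gaussian noise whose standard deviation is a fixed coefficient of
variation (CoV) times the noise-free value.

Each reaction column has 2-4 participating metabolites with coefficient
magnitudes in {1, 2} and at least one substrate and one product (mixed
signs).  Columns are drawn independently; rows the draw leaves uncovered
then receive one extra entry in a randomly chosen column with spare
capacity, and the whole matrix is rejected and resampled if it is rank
deficient.  All sampling is a pure function of the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .misspec import CandidateBlock, OmittedBlock
from .stoichio import MetabolicModel

_RANK_ATTEMPTS = 100


@dataclass(frozen=True)
class NetworkSpec:
    """Dimensions and sparsity of a random internal stoichiometric matrix."""

    m: int
    n_internal: int
    n_exchange: int
    participants: tuple[int, int] = (2, 4)
    magnitudes: tuple[float, ...] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_exchange > self.m:
            raise ValueError("n_exchange cannot exceed the metabolite count")
        if self.n_internal > self.m:
            raise ValueError("overdetermined MFA requires m >= n_internal")
        lo, hi = self.participants
        if not (1 <= lo <= hi <= self.m):
            raise ValueError("invalid participant range")
        # the unmeasured block S_I,NE is (m - n_exchange) x n_internal; its
        # null space has dimension >= n_internal - (m - n_exchange), which
        # must be positive for the flux sampler to have anything to draw.
        if self.n_internal - (self.m - self.n_exchange) < 1:
            raise ValueError(
                "null space of the unmeasured block would be trivial: need "
                "n_internal > m - n_exchange")


@dataclass
class ExchangeBlocks:
    """Exchange structure of a synthetic network: S_E = [I; 0] row split of S_I."""

    S_E: np.ndarray
    S_I: np.ndarray
    S_I_E: np.ndarray   # first m_E rows of S_I (measured balances)
    S_I_NE: np.ndarray  # remaining rows (intracellular-only balances)
    n_exchange: int


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _sample_column(m: int, spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.participants
    count = int(rng.integers(lo, hi + 1))
    rows = rng.choice(m, size=count, replace=False)
    mags = rng.choice(spec.magnitudes, size=count)
    signs = rng.choice([-1.0, 1.0], size=count)
    if count >= 2 and np.all(signs == signs[0]):
        signs[rng.integers(count)] *= -1.0  # force at least one substrate and product
    col = np.zeros(m)
    col[rows] = signs * mags
    return col


def _sample_matrix(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    m, n = spec.m, spec.n_internal
    S = np.column_stack([_sample_column(m, spec, rng) for _ in range(n)])
    # coverage repair: give each untouched species one entry in a column
    # that still has room below the participant cap
    _, hi = spec.participants
    for i in np.flatnonzero(~np.any(S, axis=1)):
        room = np.flatnonzero(np.count_nonzero(S, axis=0) < hi)
        j = int(rng.choice(room if room.size else np.arange(n)))
        S[i, j] = float(rng.choice(spec.magnitudes) * rng.choice([-1.0, 1.0]))
    return S


def random_stoichiometry(spec: NetworkSpec, seed=None) -> MetabolicModel:
    """Draw a full-column-rank internal stoichiometric matrix.

    Metabolites are labelled ``M0001``..; reactions ``R0001``..  Raises after
    a bounded number of rank-rejection attempts (loosen the sparsity range if
    this triggers).
    """
    rng = _rng(spec.seed if seed is None else seed)
    for _ in range(_RANK_ATTEMPTS):
        S = _sample_matrix(spec, rng)
        if np.linalg.matrix_rank(S) == spec.n_internal:
            return MetabolicModel(
                metabolite_ids=[f"M{i + 1:04d}" for i in range(spec.m)],
                reaction_ids=[f"R{j + 1:04d}" for j in range(spec.n_internal)],
                S=S,
            )
    raise RuntimeError(
        f"no full-column-rank matrix in {_RANK_ATTEMPTS} attempts; "
        "loosen the participant range or magnitudes")


def attach_exchanges(model: MetabolicModel, n_exchange: int) -> ExchangeBlocks:
    """Designate the first ``n_exchange`` metabolites as measured exchanges.

    Builds the block exchange matrix ``S_E = [I; 0]`` and splits ``S_I`` into
    its measured (``S_I,E``) and unmeasured (``S_I,NE``) row blocks.
    """
    m = model.n_metabolites
    if n_exchange > m:
        raise ValueError("n_exchange cannot exceed the metabolite count")
    S_E = np.vstack([np.eye(n_exchange), np.zeros((m - n_exchange, n_exchange))])
    return ExchangeBlocks(S_E=S_E, S_I=model.S,
                          S_I_E=model.S[:n_exchange],
                          S_I_NE=model.S[n_exchange:],
                          n_exchange=n_exchange)


def sample_internal_fluxes(S_I_NE: np.ndarray, seed=None) -> np.ndarray:
    """Draw internal fluxes from the null space of the unmeasured block.

    ``v_I = B c`` with B an orthonormal null-space basis of ``S_I,NE`` and
    ``c`` uniform on (-1, 1) per coordinate, so the intracellular-only
    balances close exactly.
    """
    rng = _rng(seed)
    B = sla.null_space(np.asarray(S_I_NE, dtype=float))
    if B.shape[1] == 0:
        raise ValueError("the unmeasured block has a trivial null space; "
                         "resample the network")
    c = rng.uniform(-1.0, 1.0, size=B.shape[1])
    return B @ c


def noise_free_measurements(v_I: np.ndarray, blocks: ExchangeBlocks) -> np.ndarray:
    """The exact response vector: ``y = [S_I,E v_I; 0]`` (= -S_E v_E)."""
    m_E = blocks.n_exchange
    y = np.zeros(blocks.S_I.shape[0])
    y[:m_E] = blocks.S_I_E @ v_I
    return y


def simulate_measurements(v_I: np.ndarray, blocks: ExchangeBlocks, cov: float,
                          seed=None, homoscedastic: bool = False) -> np.ndarray:
    """Contaminate the measured rows of y with zero-mean Gaussian noise.

    Default noise is CoV-scaled: ``sd_i = cov * |y_i|`` on the measured rows
    (zero-valued noise-free entries therefore receive no noise).  With
    ``homoscedastic`` every measured row instead gets the same sd,
    ``cov * mean(|y_measured|)``.  Unmeasured rows are exactly zero.
    """
    if cov < 0:
        raise ValueError("cov must be nonnegative")
    rng = _rng(seed)
    y = noise_free_measurements(v_I, blocks)
    m_E = blocks.n_exchange
    if cov == 0:
        return y
    if homoscedastic:
        sd = np.full(m_E, cov * np.mean(np.abs(y[:m_E])))
    else:
        sd = cov * np.abs(y[:m_E])
    noisy = y.copy()
    noisy[:m_E] += rng.normal(0.0, 1.0, size=m_E) * sd
    return noisy


def make_misspecified(model: MetabolicModel, v_I: np.ndarray, n_remove: int,
                      seed=None) -> tuple[MetabolicModel, OmittedBlock]:
    """Randomly drop internal reactions, returning the reduced model and truth.

    The removed columns and their true fluxes form the omitted block used to
    quantify bias and to build the truth-Z detection arm.  Column removal
    preserves full column rank; a species may lose all its reactions (its
    balance row simply becomes uninformative), so orphan checking is off.
    """
    rng = _rng(seed)
    n = model.n_reactions
    if not 0 <= n_remove < n:
        raise ValueError("n_remove must be in [0, n_reactions)")
    removed = np.sort(rng.choice(n, size=n_remove, replace=False))
    keep = np.setdiff1d(np.arange(n), removed)
    v_I = np.asarray(v_I, dtype=float).ravel()
    reduced = MetabolicModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=[model.reaction_ids[j] for j in keep],
        S=model.S[:, keep],
        check_orphans=False,
    )
    omitted = OmittedBlock(
        S_O=model.S[:, removed] if n_remove else np.empty((model.n_metabolites, 0)),
        v_O=v_I[removed] if n_remove else np.empty(0),
        reaction_ids=[model.reaction_ids[j] for j in removed],
    )
    return reduced, omitted


def make_decoy_reactions(model: MetabolicModel, size: int, spec: NetworkSpec,
                         seed=None, design: np.ndarray | None = None,
                         max_attempts: int = _RANK_ATTEMPTS) -> CandidateBlock:
    """Sample decoy candidate reactions absent from the true network.

    Decoy columns come from the same sparsity model and never duplicate a
    column of ``model``.  ``[design Z]`` must have full column rank
    (rejection resampled), where ``design`` is the matrix the decoys will be
    tested against -- the reduced internal matrix in the false-positive arm
    of the detection study; defaults to the model's own matrix.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = _rng(seed)
    m = model.n_metabolites
    existing = model.S
    design = existing if design is None else np.asarray(design, dtype=float)
    for _ in range(max_attempts):
        Z = np.column_stack([_sample_column(m, spec, rng) for _ in range(size)])
        dup = any(np.array_equal(Z[:, j], existing[:, i])
                  for j in range(size) for i in range(existing.shape[1]))
        if dup:
            continue
        combined = np.column_stack([design, Z])
        if np.linalg.matrix_rank(combined) == combined.shape[1]:
            return CandidateBlock(
                Z=Z, reaction_ids=[f"D{j + 1:04d}" for j in range(size)])
    raise RuntimeError(f"no valid decoy block in {max_attempts} attempts")


@dataclass
class SimulatedDataset:
    """One complete synthetic misspecification instance."""

    model: MetabolicModel          # full (true) internal matrix
    blocks: ExchangeBlocks
    v_I: np.ndarray                # true internal fluxes
    y: np.ndarray                  # noisy response vector
    reduced: MetabolicModel        # model with omitted reactions removed
    omitted: OmittedBlock
    decoys: CandidateBlock | None = None
    sd: np.ndarray = field(default_factory=lambda: np.empty(0))


def simulate_dataset(spec: NetworkSpec, n_omit: int, cov: float, seed,
                     with_decoys: bool = True,
                     homoscedastic: bool = False) -> SimulatedDataset:
    """Generate one detection-study replicate from independent seed streams.

    Streams (network, fluxes, noise, removal, decoys) are spawned from the
    seed so that e.g. changing the noise level does not change the network.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = ss.spawn(5)
    net_rng, flux_rng, noise_rng, rm_rng, decoy_rng = map(
        np.random.default_rng, streams)
    for _ in range(_RANK_ATTEMPTS):
        model = random_stoichiometry(spec, seed=net_rng)
        blocks = attach_exchanges(model, spec.n_exchange)
        if sla.null_space(blocks.S_I_NE).shape[1] > 0:
            break
    else:  # pragma: no cover - guaranteed non-trivial for valid specs
        raise RuntimeError("could not generate a network with usable null space")
    v_I = sample_internal_fluxes(blocks.S_I_NE, seed=flux_rng)
    y = simulate_measurements(v_I, blocks, cov, seed=noise_rng,
                              homoscedastic=homoscedastic)
    reduced, omitted = make_misspecified(model, v_I, n_omit, seed=rm_rng)
    decoys = None
    if with_decoys and n_omit > 0:
        decoys = make_decoy_reactions(model, n_omit, spec, seed=decoy_rng,
                                      design=reduced.S)
    y_free = noise_free_measurements(v_I, blocks)
    if homoscedastic:
        sd = np.full(spec.n_exchange,
                     cov * np.mean(np.abs(y_free[:spec.n_exchange])))
    else:
        sd = cov * np.abs(y_free[:spec.n_exchange])
    return SimulatedDataset(model=model, blocks=blocks, v_I=v_I, y=y,
                            reduced=reduced, omitted=omitted, decoys=decoys,
                            sd=sd)
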