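"""SOZ inference: top-percentile candidates intersected with an empirical null.

The pipeline for one measure (DI or GC):

1. extract one 10-s ictal block per annotated seizure, preprocess each,
   estimate a causal graph per block and average them;
2. score nodes with hub-minus-authority PageRank;
3. ``S0`` = nodes in the top ``p0`` percentile of the scores (default 10);
4. build an empirical null: R times (default 200), sample ``N_S`` random
   rest blocks, run the identical graph + scoring machinery, and store the
   resulting score vector as one null column;
5. ``S1`` = nodes whose ictal score sits in the top ``p1`` percentile
   (default 5) of their own null row; the inference is ``S = S0 ∩ S1``.

The non-parametric DI graph is tried first; if its intersection is empty the
whole procedure (including a fresh null) is repeated with the parametric GC
graph, and the algorithm terminates even if that set is empty too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import preprocess
from .causal import CausalGraph, EstimatorParams, average_graphs, estimate_graph
from .ranking import ScoreVector, node_scores
from .recordings import Block, RecordingSession, extract_ictal_blocks, sample_rest_blocks

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceParams",
    "NullDistribution",
    "SOZInference",
    "top_percentile_set",
    "build_null",
    "significant_set",
    "infer_soz",
]


@dataclass
class InferenceParams:
    """Everything the end-to-end localization needs besides the session."""

    p0: float = 10.0  # top percentile of ictal scores kept as candidates
    p1: float = 5.0  # top percentile of each node's empirical null
    reps: int = 200  # null repetitions R
    alpha: float = 0.85
    block_length: float = 10.0
    guard: float = 120.0  # rest blocks stay this far from any seizure
    cutoff: float | None = 100.0  # low-pass edge; None skips band limiting
    target_fs: float = 200.0
    di: EstimatorParams = field(default_factory=lambda: EstimatorParams(measure="di"))
    gc: EstimatorParams = field(default_factory=lambda: EstimatorParams(measure="gc"))
    null_pool: int | None = None  # if set, resample reps from this many rest graphs
    measure: str = "auto"  # "auto" (DI then GC fallback) | "di" | "gc"

    def __post_init__(self):
        if not (0 < self.p0 <= 100) or not (0 < self.p1 <= 100):
            raise ValueError("percentiles must lie in (0, 100]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.measure not in ("auto", "di", "gc"):
            raise ValueError(f"unknown measure {self.measure!r}")

    def estimator(self, measure: str) -> EstimatorParams:
        return self.di if measure == "di" else self.gc


@dataclass
class NullDistribution:
    """N x R matrix of rest-block scores; row i is the empirical null of node i."""

    samples: np.ndarray
    measure: str
    seed_record: object = None
    failed_repetitions: int = 0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    @property
    def n_reps(self) -> int:
        return self.samples.shape[1]


@dataclass
class SOZInference:
    """Final inference: S = S0 ∩ S1 plus full provenance."""

    s0: set[str]
    s1: set[str]
    soz: set[str]
    measure_used: str
    scores: ScoreVector
    null: NullDistribution
    graph: CausalGraph

    def to_dict(self) -> dict:
        return {
            "S0": sorted(self.s0),
            "S1": sorted(self.s1),
            "S": sorted(self.soz),
            "measure_used": self.measure_used,
        }


def top_percentile_set(
    s: np.ndarray, p0: float, labels: list[str] | None = None
) -> set:
    """Nodes with score >= the (100 - p0)-th linear-interpolation percentile.

    The boundary is closed, so ties at the threshold are all included; with
    all scores equal every node is returned.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    q = np.percentile(s, 100.0 - p0)
    idx = np.flatnonzero(s >= q)
    if labels is None:
        return set(idx.tolist())
    return {labels[i] for i in idx}


def significant_set(
    s: np.ndarray, null: NullDistribution, p1: float, labels: list[str] | None = None
) -> set:
    """Nodes whose score reaches the top p1 percentile of their own null row."""
    s = np.asarray(s, dtype=float)
    if null.samples.shape[0] != s.size:
        raise ValueError(
            f"null has {null.samples.shape[0]} rows for {s.size} scores"
        )
    if null.n_reps < 20:
        warnings.warn(
            f"only {null.n_reps} null repetitions; the {p1:g}% tail is poorly resolved"
        )
    thresh = np.percentile(null.samples, 100.0 - p1, axis=1)
    idx = np.flatnonzero(s >= thresh)
    if labels is None:
        return set(idx.tolist())
    return {labels[i] for i in idx}


# ---------------------------------------------------------------------------
# Pipeline plumbing
# ---------------------------------------------------------------------------


def _prepare(block: Block, params: InferenceParams) -> Block:
    # band-limit only when the recording actually carries content above the
    # analyzed band; a block already at (or below) the working rate is used as-is
    if params.cutoff is not None and block.fs > max(2 * params.cutoff, params.target_fs):
        block = preprocess.band_limit(block, params.cutoff, params.target_fs)
    return preprocess.standardize(block)


def _score_blocks(
    blocks: list[Block], measure: str, params: InferenceParams, labels: list[str]
) -> tuple[ScoreVector, CausalGraph]:
    graphs = [
        estimate_graph(_prepare(b, params), params.estimator(measure), labels)
        for b in blocks
    ]
    mean_graph = average_graphs(graphs)
    return node_scores(mean_graph.weights, params.alpha, labels), mean_graph


def _rest_graph_scores(
    session, measure, params, rng, n_blocks
) -> np.ndarray:
    blocks = sample_rest_blocks(
        session, n_blocks, params.block_length, rng, params.guard
    )
    scores, _ = _score_blocks(blocks, measure, params, session.channel_labels)
    return scores.s


def build_null(
    session: RecordingSession,
    measure: str,
    params: InferenceParams,
    rng: np.random.Generator | int | None = None,
) -> NullDistribution:
    """Empirical per-node null from R independent draws of N_S rest blocks.

    Each repetition mirrors the ictal computation exactly: sample ``N_S``
    rest blocks, preprocess, estimate one graph per block with ``measure``,
    average, and score.  A repetition that fails (e.g. a flat channel in an
    unlucky window) is resampled and counted.  With ``params.null_pool`` set,
    a pool of that many single-rest-block graphs is computed once and each
    repetition averages ``N_S`` graphs drawn from the pool without
    replacement — a cheaper approximation used for the expensive k-NN DI
    measure at desk scale.
    """
    rng = np.random.default_rng(rng)
    n_s = session.n_seizures
    if n_s < 1:
        raise ValueError("session has no annotated seizures (N_S = 0)")
    n = session.n_channels
    cols = np.empty((n, params.reps))
    failed = 0

    if params.null_pool is not None:
        pool_size = max(params.null_pool, n_s)
        pool = []
        while len(pool) < pool_size:
            try:
                block = sample_rest_blocks(
                    session, 1, params.block_length, rng, params.guard
                )[0]
                pool.append(
                    estimate_graph(
                        _prepare(block, params),
                        params.estimator(measure),
                        session.channel_labels,
                    )
                )
            except ValueError as exc:
                failed += 1
                logger.warning("resampling failed pool graph: %s", exc)
                if failed > 10 * pool_size:
                    raise
        for r in range(params.reps):
            chosen = rng.choice(pool_size, size=n_s, replace=False)
            g = average_graphs([pool[c] for c in chosen])
            cols[:, r] = node_scores(g.weights, params.alpha).s
    else:
        r = 0
        while r < params.reps:
            try:
                cols[:, r] = _rest_graph_scores(session, measure, params, rng, n_s)
                r += 1
            except ValueError as exc:
                failed += 1
                logger.warning("resampling failed null repetition: %s", exc)
                if failed > 10 * params.reps:
                    raise
    return NullDistribution(cols, measure, failed_repetitions=failed)


def _infer_single_measure(
    session: RecordingSession,
    measure: str,
    params: InferenceParams,
    rng: np.random.Generator,
) -> SOZInference:
    blocks = extract_ictal_blocks(session, params.block_length)
    if not blocks:
        raise ValueError("no usable ictal blocks in this session")
    labels = session.channel_labels
    scores, graph = _score_blocks(blocks, measure, params, labels)
    s0 = top_percentile_set(scores.s, params.p0, labels)
    null = build_null(session, measure, params, rng)
    s1 = significant_set(scores.s, null, params.p1, labels)
    return SOZInference(
        s0=s0,
        s1=s1,
        soz=s0 & s1,
        measure_used=measure,
        scores=scores,
        null=null,
        graph=graph,
    )


def infer_soz(
    session: RecordingSession,
    params: InferenceParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> SOZInference:
    """Full localization with the DI-first / GC-fallback measure selection.

    Returns the DI inference when it is nonempty; otherwise the entire
    procedure is rerun with GC (including a fresh GC null) and that result
    is returned, even if empty.
    """
    params = params or InferenceParams()
    rng = np.random.default_rng(rng)
    if params.measure in ("di", "gc"):
        return _infer_single_measure(session, params.measure, params, rng)
    di_result = _infer_single_measure(session, "di", params, rng)
    if di_result.soz:
        return di_result
    logger.info("DI inference empty; falling back to the GC graph")
    return _infer_single_measure(session, "gc", params, rng)
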