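"""Single-sample mutation-based pathway enrichment scores (ssMutPES).

Genes are ranked by their steady-state propagation weights (descending) and
each pathway is scored with a weighted Kolmogorov-Smirnov running sum: walking
down the ranked list L, the in-pathway fraction accumulates |r_j|^p / N_R for
pathway members (N_R the total in-pathway weight mass) and the out-of-pathway
fraction accumulates 1 / N_NotP for the rest. The score is the maximum of
F_InP(i) - F_NotP(i) over all positions, floored at zero, so every ssMutPES
lies in [0, 1]; a high score means the pathway's genes concentrate at the top
of the list, i.e. pathway activity plausibly induced by the sample's
mutations. The weight exponent p defaults to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MutationProfile, PathwayCollection
from .network import PPINetwork
from .propagation import GlobalWeightVector, initial_vector, rwr
from .seeds import local_weights, map_seeds

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateCellError",
    "RankedGeneList",
    "ScoreMatrix",
    "ScoringParams",
    "SampleScore",
    "rank_genes",
    "ssmutpes",
    "score_sample",
    "score_cohort",
    "pathway_node_masks",
]

SKIP_NO_PATHWAY_GENES = "no pathway genes in network"
SKIP_DEGENERATE_COMPLEMENT = "degenerate complement"
SKIP_ZERO_WEIGHT_MASS = "zero pathway weight mass"


class DegenerateCellError(ValueError):
    """A (pathway, sample) cell cannot be scored; ``reason`` says why."""

    def __init__(self, reason: str) -> None:
        super().__init__(reason)
        self.reason = reason


@dataclass
class ScoringParams:
    """Tunable parameters of the scoring pipeline.

    alpha: log base of the local seed weighting (> 1).
    restart: RWR restart probability c in (0, 1).
    tol: L1 convergence tolerance of the walk.
    p_exp: exponent on the global weights in the KS running sum.
    """

    alpha: float = 2.0
    restart: float = 0.7
    tol: float = 1e-10
    max_iter: int = 10000
    p_exp: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if not 0.0 < self.restart < 1.0:
            raise ValueError("restart probability must be in (0, 1)")
        if self.p_exp < 0:
            raise ValueError("p_exp must be >= 0")


@dataclass
class RankedGeneList:
    """Network genes ordered by descending normalized global weight."""

    genes: tuple[str, ...]
    weights: np.ndarray  # non-increasing, unit sum


@dataclass
class SampleScore:
    """One sample's pathway scores plus bookkeeping."""

    sample_id: str
    scores: pd.Series
    skipped: dict[str, str]
    n_seeds: int
    n_unmapped: int
    no_seeds: bool
    iterations: int | None


@dataclass
class ScoreMatrix:
    """Pathways x samples ssMutPES matrix with skip/failure bookkeeping.

    ``skipped`` maps (pathway_id, sample_id) to a reason code for cells that
    could not be scored (stored as 0); ``no_seed_samples`` lists samples whose
    columns are all-zero because no mutation mapped into the network;
    ``failures`` maps sample ids whose scoring raised to the error message
    (their columns are NaN).
    """

    frame: pd.DataFrame
    skipped: dict[tuple[str, str], str] = field(default_factory=dict)
    no_seed_samples: tuple[str, ...] = ()
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)


def rank_genes(gw: GlobalWeightVector, net: PPINetwork) -> RankedGeneList:
    """Sort genes by global weight, descending; ties by gene symbol ascending.

    Weights are renormalized to unit sum (idempotent: the steady-state vector
    already sums to 1).
    """
    order = np.lexsort((net.node_array, -gw.p))
    weights = gw.p[order]
    total = weights.sum()
    if total <= 0:
        raise ValueError("global weight vector has no mass")
    return RankedGeneList(
        genes=tuple(net.node_array[order]), weights=weights / total
    )


def _running_sum_max(weights: np.ndarray, in_pathway: np.ndarray, p_exp: float) -> float:
    """Max over positions of F_InP - F_NotP for an already-sorted list."""
    n = in_pathway.size
    n_hit = int(in_pathway.sum())
    if n_hit == 0:
        raise DegenerateCellError(SKIP_NO_PATHWAY_GENES)
    if n_hit == n:
        raise DegenerateCellError(SKIP_DEGENERATE_COMPLEMENT)
    wp = np.abs(weights) ** p_exp
    mass = float(wp[in_pathway].sum())
    if mass == 0.0:
        raise DegenerateCellError(SKIP_ZERO_WEIGHT_MASS)
    f_in = np.cumsum(np.where(in_pathway, wp, 0.0)) / mass
    f_not = np.cumsum(np.where(in_pathway, 0.0, 1.0)) / (n - n_hit)
    return max(float(np.max(f_in - f_not)), 0.0)


def ssmutpes(ranked: RankedGeneList, pathway, p_exp: float = 1.0) -> float:
    """ssMutPES of one pathway against one ranked gene list.

    Raises :class:`DegenerateCellError` when the pathway has no gene in the
    list, covers the whole list, or carries zero weight mass.
    """
    members = set(pathway)
    in_pathway = np.fromiter(
        (g in members for g in ranked.genes), dtype=bool, count=len(ranked.genes)
    )
    return _running_sum_max(ranked.weights, in_pathway, p_exp)


def pathway_node_masks(net: PPINetwork, pathways: PathwayCollection) -> dict[str, np.ndarray]:
    """Boolean membership masks over net.nodes, one per pathway.

    Pathway genes absent from the network are dropped (counts logged).
    """
    masks: dict[str, np.ndarray] = {}
    for pid, genes in pathways.items():
        mask = np.zeros(net.n_nodes, dtype=bool)
        n_absent = 0
        for g in genes:
            i = net.index.get(g)
            if i is None:
                n_absent += 1
            else:
                mask[i] = True
        if n_absent:
            logger.debug("pathway %s: %d gene(s) not in the network", pid, n_absent)
        masks[pid] = mask
    return masks


def score_sample(
    profile: MutationProfile,
    net: PPINetwork,
    pathways: PathwayCollection,
    params: ScoringParams | None = None,
    _masks: dict[str, np.ndarray] | None = None,
) -> SampleScore:
    """Full per-sample pipeline: seeds -> local weights -> RWR -> rank -> KS.

    A sample with no seeds yields an all-zero column (with a warning); a
    degenerate (pathway, sample) cell is stored as 0 with a reason code.
    """
    params = params or ScoringParams()
    pids = list(pathways.ids)
    seeds = map_seeds(profile, net)
    n_unmapped = len(profile.genes) - len(seeds)
    if not seeds:
        return SampleScore(
            sample_id=profile.sample_id,
            scores=pd.Series(0.0, index=pids, name=profile.sample_id),
            skipped={},
            n_seeds=0,
            n_unmapped=n_unmapped,
            no_seeds=True,
            iterations=None,
        )
    sw = local_weights(seeds, net, alpha=params.alpha, sample_id=profile.sample_id)
    p0 = initial_vector(sw, net)
    gw = rwr(
        p0,
        net,
        c=params.restart,
        tol=params.tol,
        max_iter=params.max_iter,
        sample_id=profile.sample_id,
    )
    order = np.lexsort((net.node_array, -gw.p))
    weights = gw.p[order]
    weights = weights / weights.sum()
    masks = _masks if _masks is not None else pathway_node_masks(net, pathways)

    values: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for pid in pids:
        try:
            values[pid] = _running_sum_max(weights, masks[pid][order], params.p_exp)
        except DegenerateCellError as exc:
            skipped[pid] = exc.reason
            values[pid] = 0.0
    return SampleScore(
        sample_id=profile.sample_id,
        scores=pd.Series(values, index=pids, name=profile.sample_id),
        skipped=skipped,
        n_seeds=len(seeds),
        n_unmapped=n_unmapped,
        no_seeds=False,
        iterations=gw.iterations,
    )


def score_cohort(
    cohort,
    net: PPINetwork,
    pathways: PathwayCollection,
    params: ScoringParams | None = None,
) -> ScoreMatrix:
    """Score every sample; columns equal independent score_sample calls, in order.

    Per-sample failures are recorded (column NaN) and the rest proceed.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    sample_ids = [p.sample_id for p in cohort]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in cohort")
    params = params or ScoringParams()
    masks = pathway_node_masks(net, pathways)
    pids = list(pathways.ids)

    columns: dict[str, pd.Series] = {}
    skipped: dict[tuple[str, str], str] = {}
    no_seeds: list[str] = []
    failures: dict[str, str] = {}
    for profile in cohort:
        try:
            result = score_sample(profile, net, pathways, params, _masks=masks)
        except Exception as exc:  # record and continue with other samples
            logger.error("sample %s failed: %r", profile.sample_id, exc)
            failures[profile.sample_id] = repr(exc)
            columns[profile.sample_id] = pd.Series(np.nan, index=pids)
            continue
        columns[profile.sample_id] = result.scores
        for pid, reason in result.skipped.items():
            skipped[(pid, profile.sample_id)] = reason
        if result.no_seeds:
            no_seeds.append(profile.sample_id)
    frame = pd.DataFrame(columns, index=pids).loc[:, sample_ids]
    frame.index.name = "pathway"
    return ScoreMatrix(
        frame=frame,
        skipped=skipped,
        no_seed_samples=tuple(no_seeds),
        failures=failures,
    )
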