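"""Downstream subtype discovery from ssMutPES profiles.

Stages: (1) univariate Cox proportional-hazards screen keeping pathways whose
score is associated with overall survival (Wald p < alpha_level, HR direction
reported); (2) sample-sample similarity from Euclidean distances between
screened score vectors through a Gaussian kernel with median-heuristic
bandwidth; (3) spectral clustering with the number of clusters selected by
the mean silhouette index over a candidate range (default 2..6); (4)
multi-group log-rank comparison of the recovered subtypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_score

from .io import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "CoxScreenResult",
    "SampleSimilarity",
    "SubtypeAssignment",
    "LogrankResult",
    "read_survival_table",
    "write_survival_table",
    "cox_screen",
    "similarity_matrix",
    "choose_k_and_cluster",
    "logrank_compare",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Overall-survival follow-up for one sample (time in days)."""

    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")


def read_survival_table(path) -> list[SurvivalRecord]:
    """Read a survival TSV: sample_id, time, event(0/1); optional header."""
    records: list[SurvivalRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            if lineno == 1 and fields[0].strip().lower() in {"sample", "sample_id"}:
                continue
            try:
                time = float(fields[1])
                event = bool(int(fields[2]))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: time/event not numeric: {fields[1:3]}"
                ) from None
            records.append(SurvivalRecord(fields[0].strip(), time, event))
    return records


def write_survival_table(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for rec in records:
            fh.write(f"{rec.sample_id}\t{rec.time!r}\t{int(rec.event)}\n")


@dataclass
class CoxScreenResult:
    """Per-pathway univariate Cox fits and the set passing the screen."""

    table: pd.DataFrame  # columns: pathway, hazard_ratio, p (+ q with BH)
    passed: tuple[str, ...]
    skipped: dict[str, str] = field(default_factory=dict)
    alpha_level: float = 0.05


def _survival_frame(surv) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in surv],
            "time": [r.time for r in surv],
            "event": [int(r.event) for r in surv],
        }
    ).set_index("sample_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in survival records")
    return df


def cox_screen(scores, surv, alpha_level: float = 0.05, bh: bool = False) -> CoxScreenResult:
    """Univariate Cox screen of each pathway score against overall survival.

    ``scores`` is a ScoreMatrix or pathway x sample DataFrame. Zero-variance
    pathways are skipped with a reason; pathways pass with Wald p below
    ``alpha_level`` (on BH-adjusted q-values when ``bh`` is set). Hazard
    ratios above 1 mark risk pathways, below 1 protective ones.
    """
    frame = getattr(scores, "frame", scores)
    surv_df = _survival_frame(surv)
    common = [s for s in frame.columns if s in surv_df.index]
    if len(common) < 3:
        raise ValueError("need at least 3 samples with both scores and survival")
    surv_df = surv_df.loc[common]
    if surv_df["event"].sum() < 2:
        raise ValueError("need at least 2 observed events for the Cox screen")

    rows = []
    skipped: dict[str, str] = {}
    for pid in frame.index:
        x = frame.loc[pid, common].astype(float)
        if x.isna().any():
            skipped[pid] = "missing scores"
            continue
        if float(np.var(x.to_numpy())) == 0.0:
            skipped[pid] = "zero score variance"
            continue
        data = pd.DataFrame(
            {"time": surv_df["time"], "event": surv_df["event"], "score": x.to_numpy()},
            index=common,
        )
        fitter = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(data, duration_col="time", event_col="event")
        except Exception as exc:
            skipped[pid] = f"fit failed: {exc}"
            continue
        rows.append(
            (
                pid,
                float(np.exp(fitter.params_["score"])),
                float(fitter.summary.loc["score", "p"]),
            )
        )
    table = pd.DataFrame(rows, columns=["pathway", "hazard_ratio", "p"])
    if bh and not table.empty:
        table["q"] = false_discovery_control(table["p"].to_numpy(), method="bh")
        passed = tuple(table.loc[table["q"] < alpha_level, "pathway"])
    else:
        passed = tuple(table.loc[table["p"] < alpha_level, "pathway"])
    if not passed:
        logger.warning(
            "no pathway passed the Cox screen at alpha %.3g; caller may fall "
            "back to all pathways",
            alpha_level,
        )
    return CoxScreenResult(table=table, passed=passed, skipped=skipped, alpha_level=alpha_level)


@dataclass
class SampleSimilarity:
    """Gaussian-kernel similarity over Euclidean score distances."""

    sample_ids: tuple[str, ...]
    similarity: np.ndarray
    distance: np.ndarray
    sigma: float


def similarity_matrix(scores) -> SampleSimilarity:
    """Sample-sample similarity s = exp(-d^2 / (2 sigma^2)).

    d is the Euclidean distance between pathway-score vectors and sigma the
    median of the nonzero pairwise distances (bandwidth heuristic). The matrix
    is symmetric with unit diagonal.
    """
    frame = getattr(scores, "frame", scores)
    if frame.shape[1] < 2 or frame.shape[0] < 1:
        raise ValueError("need at least 2 samples and 1 pathway")
    points = frame.T.to_numpy(dtype=float)
    condensed = pdist(points)
    nonzero = condensed[condensed > 0]
    if nonzero.size == 0:
        logger.warning("all samples identical: degenerate similarity matrix")
        sigma = 1.0
    else:
        sigma = float(np.median(nonzero))
    distance = squareform(condensed)
    similarity = np.exp(-(distance**2) / (2.0 * sigma**2))
    np.fill_diagonal(similarity, 1.0)
    return SampleSimilarity(
        sample_ids=tuple(frame.columns),
        similarity=similarity,
        distance=distance,
        sigma=sigma,
    )


@dataclass
class SubtypeAssignment:
    """Spectral-clustering labels (1..k) with the silhouette profile over k."""

    labels: dict[str, int]
    k: int
    silhouette_by_k: dict[int, float]


def choose_k_and_cluster(
    sim: SampleSimilarity,
    k_range=range(2, 7),
    random_state: int = 0,
) -> SubtypeAssignment:
    """Spectral-cluster at each candidate k; keep the best mean silhouette.

    Silhouettes are computed on the Euclidean distances. Ties favor the
    smaller k. Labels are renumbered 1..k by order of first appearance so the
    assignment is deterministic given ``random_state``.
    """
    n = len(sim.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")

    silhouette_by_k: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        model = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            random_state=random_state,
            assign_labels="kmeans",
            n_init=10,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = model.fit_predict(sim.similarity)
        labelings[k] = labels
        if len(np.unique(labels)) < 2:
            silhouette_by_k[k] = float("-inf")
        else:
            silhouette_by_k[k] = float(
                silhouette_score(sim.distance, labels, metric="precomputed")
            )
    best_k = max(k_range, key=lambda k: (silhouette_by_k[k], -k))
    raw = labelings[best_k]
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[int(lab)] = len(remap) + 1
    labels = {sid: remap[int(lab)] for sid, lab in zip(sim.sample_ids, raw)}
    return SubtypeAssignment(labels=labels, k=best_k, silhouette_by_k=silhouette_by_k)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    degrees_of_freedom: int


def logrank_compare(assign: SubtypeAssignment, surv) -> LogrankResult:
    """Multi-group log-rank test of survival differences between subtypes."""
    surv_df = _survival_frame(surv)
    common = [s for s in assign.labels if s in surv_df.index]
    groups = pd.Series({s: assign.labels[s] for s in common})
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("log-rank comparison needs at least 2 clusters")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"cluster(s) {small} have fewer than 2 samples")
    surv_df = surv_df.loc[common]
    result = multivariate_logrank_test(
        surv_df["time"].to_numpy(),
        groups.to_numpy(),
        surv_df["event"].to_numpy(),
    )
    return LogrankResult(
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        degrees_of_freedom=len(counts) - 1,
    )
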