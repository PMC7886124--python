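"""Five-step functional typing cascade.

1. Cells with both chirp and flash responses are assigned to the five
   dominant clusters (transient/sustained ON/OFF, ON-OFF) by rule:
   polarity, transiency against 400 ms, and the median chirp response for
   high vs low temporal frequencies.
2. Chirp-responding, flash-silent cells are matched to the five cluster
   templates by similarity sum(|normResponse - template|), accepted when
   the similarity is within mean + SD of the step-1 assignees.
3. Remaining chirp responders are grouped by flash polarity into clusters
   6 (ON), 7 (OFF) and 8 (no flash response).
4. Chirp-nonresponders are k-means clustered on their normalized 24-entry
   grating maps (squared Euclidean distance, 1000 restarts); the cluster
   count is chosen by the Calinski-Harabasz and Davies-Bouldin indices
   (rank sum, smaller k on ties), giving clusters 9..8+k.
5. Cells never probed with the chirp are assigned to the nearest cluster
   mean grating map, accepted when within the 95th percentile of member
   similarities; otherwise they stay unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .indices import CellProfile
from .metrics import ChirpSpectrum, FlashPSTH, GratingResponseMap
from .synthetic import ClusterTemplate

__all__ = [
    "CellRecord",
    "ClusterAssignment",
    "TemplateLibrary",
    "KMeansModel",
    "PipelineResult",
    "chirp_high_low",
    "assign_step1",
    "similarity",
    "assign_step2",
    "group_step3",
    "cluster_step4",
    "assign_step5",
    "run_pipeline",
]

#: split of the chirp ramp band into low/high temporal-frequency halves (Hz)
CHIRP_SPLIT_HZ = 4.25
TRANSIENCY_RULE_MS = 400.0
SUSTAINED_ON_MARGIN = 0.2

STEP1_CLUSTERS = {
    "transient_on": 1,
    "transient_off": 2,
    "sustained_on": 3,
    "sustained_off": 4,
    "on_off_transient": 5,
}


@dataclass
class CellRecord:
    """Everything the cascade needs to know about one unit."""

    unit_id: str
    profile: CellProfile
    grating_map: Optional[GratingResponseMap] = None
    chirp_spectrum: Optional[ChirpSpectrum] = None
    chirp_trace: Optional[np.ndarray] = None  # 10 ms bins, max-normalized
    flash_trace: Optional[np.ndarray] = None  # 10 ms bins, max-normalized
    flash_psth: Optional[FlashPSTH] = None
    chirp_probed: bool = True
    responds_to_chirp: bool = False

    @property
    def responds_to_gratings(self) -> bool:
        return self.grating_map is not None and self.grating_map.responsive

    @property
    def flash_polarity(self) -> Optional[str]:
        return self.profile.polarity


@dataclass(frozen=True)
class ClusterAssignment:
    unit_id: str
    cluster: Optional[int]  # 1..16 or None for unassigned/dropped
    step: Optional[int]  # 1..5
    similarity: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.cluster is not None and self.step is not None:
            # steps 1-2 assign the five dominant clusters, step 3 the flash
            # groups 6-8; step 4 yields 9..(8+k) (9-16 for the default k <= 8)
            ranges = {1: (1, 5), 2: (1, 5), 3: (6, 8), 4: (9, None), 5: (1, None)}
            lo, hi = ranges[self.step]
            if self.cluster < lo or (hi is not None and self.cluster > hi):
                raise ValueError(
                    f"cluster {self.cluster} inconsistent with step {self.step}")


@dataclass
class TemplateLibrary:
    """The five dominant templates plus per-cluster similarity statistics."""

    templates: list[ClusterTemplate]
    stats: dict[int, tuple[float, float]] = field(default_factory=dict)  # cluster -> (mean, std)

    def __post_init__(self) -> None:
        if len(self.templates) != 5:
            raise ValueError("template library needs exactly 5 templates")

    def template_for(self, cluster: int) -> ClusterTemplate:
        return self.templates[cluster - 1]


@dataclass
class KMeansModel:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    diagnostics: dict[int, tuple[float, float]]  # k -> (CH, DB)
    seed: int
    repetitions: int


@dataclass
class PipelineResult:
    assignments: list[ClusterAssignment]
    step_counts: dict[str, int]
    kmeans: Optional[KMeansModel] = None
    library: Optional[TemplateLibrary] = None


# ---------------------------------------------------------------------------
# step 1: rules
# ---------------------------------------------------------------------------

def chirp_high_low(spectrum: ChirpSpectrum,
                   split_hz: float = CHIRP_SPLIT_HZ) -> tuple[float, float]:
    """Median chirp FFT ratio over the upper and lower halves of the band."""
    lo_edge = float(spectrum.freqs[0])
    hi_edge = float(spectrum.freqs[-1])
    high = spectrum.band_median(split_hz, np.nextafter(hi_edge, np.inf))
    low = spectrum.band_median(lo_edge, split_hz)
    return high, low


def assign_step1(profile: CellProfile, spectrum: ChirpSpectrum,
                 transiency_rule_ms: float = TRANSIENCY_RULE_MS,
                 sustained_margin: float = SUSTAINED_ON_MARGIN) -> Optional[int]:
    """Apply the five assignment rules; returns cluster 1-5 or None."""
    if profile.polarity in (None, "none") or profile.transiency_ms is None:
        return None
    high, low = chirp_high_low(spectrum)
    pol, trans = profile.polarity, profile.transiency_ms
    if pol == "ON" and trans < transiency_rule_ms and high > low:
        return 1
    if pol == "OFF" and trans < transiency_rule_ms and high > low:
        return 2
    if pol == "ON" and trans >= transiency_rule_ms and (high - low) < sustained_margin:
        return 3
    if pol == "OFF" and trans >= transiency_rule_ms:
        return 4
    if pol == "ON-OFF" and trans < transiency_rule_ms and high > low:
        return 5
    return None


# ---------------------------------------------------------------------------
# step 2: template similarity
# ---------------------------------------------------------------------------

def similarity(trace: np.ndarray, template: np.ndarray) -> float:
    """Sum of absolute pointwise differences; lower is more similar."""
    trace = np.asarray(trace, dtype=float)
    template = np.asarray(template, dtype=float)
    if trace.size != template.size:
        raise ValueError("trace and template lengths differ after resampling")
    return float(np.abs(trace - template).sum())


def _cell_chirp_similarity(record: CellRecord, library: TemplateLibrary,
                           cluster: int) -> float:
    # both sides max-normalized so chirp-only comparisons are scale-free
    tpl = library.template_for(cluster).chirp_values
    peak = tpl.max()
    if peak > 0:
        tpl = tpl / peak
    trace = record.chirp_trace
    if trace.size != tpl.size:
        n = min(trace.size, tpl.size)
        if abs(trace.size - tpl.size) > 2:
            raise ValueError("chirp trace and template lengths differ")
        trace, tpl = trace[:n], tpl[:n]
    return similarity(trace, tpl)


def populate_template_stats(library: TemplateLibrary,
                            step1_records: Sequence[tuple[CellRecord, int]]) -> None:
    """Per-cluster mean/std of step-1 assignees' similarity to their template."""
    by_cluster: dict[int, list[float]] = {c: [] for c in range(1, 6)}
    for record, cluster in step1_records:
        if record.chirp_trace is not None:
            by_cluster[cluster].append(_cell_chirp_similarity(record, library, cluster))
    for c, sims in by_cluster.items():
        if sims:
            library.stats[c] = (float(np.mean(sims)), float(np.std(sims)))


def assign_step2(record: CellRecord, library: TemplateLibrary
                 ) -> tuple[Optional[int], Optional[float]]:
    """Best qualifying template cluster, or None when no threshold is met.

    Similarity is computed on the chirp segment only (these cells have no
    flash response to compare). Clusters whose step-1 population was empty
    have no threshold and are skipped with a warning.
    """
    if record.chirp_trace is None:
        return None, None
    best: tuple[Optional[int], Optional[float]] = (None, None)
    for c in range(1, 6):
        if c not in library.stats:
            warnings.warn(f"cluster {c}: no step-1 assignees, threshold undefined; skipped")
            continue
        mean_c, std_c = library.stats[c]
        sim = _cell_chirp_similarity(record, library, c)
        if sim <= mean_c + std_c and (best[1] is None or sim < best[1]):
            best = (c, sim)
    return best


# ---------------------------------------------------------------------------
# step 3: flash grouping
# ---------------------------------------------------------------------------

def group_step3(record: CellRecord) -> tuple[int, str]:
    """ON -> 6, OFF -> 7, no flash response -> 8; ON-OFF cells (not observed
    in the source data) are routed to 6 or 7 by the larger transition peak."""
    pol = record.flash_polarity
    if pol == "ON":
        return 6, ""
    if pol == "OFF":
        return 7, ""
    if pol == "ON-OFF":
        note = "ON-OFF routed by peak size"
        target = 6
        if record.flash_psth is not None:
            peaks = record.flash_psth.transition_peaks
            pos = max((p for _, s, p, _ in peaks if s > 0), default=0.0)
            neg = max((p for _, s, p, _ in peaks if s < 0), default=0.0)
            target = 6 if pos >= neg else 7
        return target, note
    return 8, ""


# ---------------------------------------------------------------------------
# step 4: k-means over grating maps
# ---------------------------------------------------------------------------

def cluster_step4(maps: Sequence[np.ndarray], seed: int,
                  k_range: tuple[int, int] = (2, 12),
                  repetitions: int = 1000) -> KMeansModel:
    """k-means (squared Euclidean, ``repetitions`` restarts) with the cluster
    count chosen by Calinski-Harabasz + Davies-Bouldin rank sum."""
    X = np.stack([np.asarray(m, dtype=float).ravel() for m in maps])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all grating maps identical")
    k_lo, k_hi = k_range
    # candidate clusters must be able to hold >= 2 cells: near-singleton
    # clusters drive Davies-Bouldin toward 0 and Calinski-Harabasz upward,
    # so an uncapped search always fragments small pools
    k_hi = min(k_hi, max(k_lo, X.shape[0] // 2), X.shape[0] - 1)
    if k_hi < k_lo:
        raise ValueError("fewer cells than the smallest candidate k")
    candidates = list(range(k_lo, k_hi + 1))
    fits: dict[int, KMeans] = {}
    diagnostics: dict[int, tuple[float, float]] = {}
    for k in candidates:
        km = KMeans(n_clusters=k, n_init=repetitions, random_state=seed)
        labels = km.fit_predict(X)
        diagnostics[k] = (calinski_harabasz_score(X, labels),
                          davies_bouldin_score(X, labels))
        fits[k] = km
    ch = np.array([diagnostics[k][0] for k in candidates])
    db = np.array([diagnostics[k][1] for k in candidates])
    # CH is maximized, DB minimized; rank both so 1 = best, break ties low-k
    ranks = rankdata(-ch, method="min") + rankdata(db, method="min")
    best_k = candidates[int(np.argmin(ranks))]
    km = fits[best_k]
    return KMeansModel(k=best_k, centroids=km.cluster_centers_,
                       labels=km.labels_.copy(), diagnostics=diagnostics,
                       seed=seed, repetitions=repetitions)


# ---------------------------------------------------------------------------
# step 5: assignment by grating-map similarity
# ---------------------------------------------------------------------------

def assign_step5(record_map: np.ndarray,
                 cluster_means: dict[int, np.ndarray],
                 member_similarities: dict[int, np.ndarray],
                 percentile: float = 95.0) -> tuple[Optional[int], Optional[float]]:
    """Nearest cluster mean map, gated by the members' similarity percentile.

    Clusters with fewer than two members have no percentile and are excluded
    as candidates.
    """
    v = np.asarray(record_map, dtype=float).ravel()
    best_c, best_sim = None, np.inf
    for c, mean_map in cluster_means.items():
        sims = member_similarities.get(c)
        if sims is None or len(sims) < 2:
            continue
        s = similarity(v, mean_map.ravel())
        if s < best_sim:
            best_c, best_sim = c, s
    if best_c is None:
        return None, None
    cutoff = float(np.percentile(member_similarities[best_c], percentile))
    if best_sim <= cutoff:
        return best_c, best_sim
    return None, best_sim


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

def run_pipeline(records: Sequence[CellRecord],
                 library: TemplateLibrary,
                 seed: int = 0,
                 k_range: tuple[int, int] = (2, 12),
                 repetitions: int = 1000) -> PipelineResult:
    """Execute steps 1-5 with the eligibility gates.

    Gates: chirp-probed cells go through steps 1-3 when they respond to the
    chirp (step 1 needs a flash response, step 2 handles flash-silent cells,
    step 3 collects the rest); chirp-nonresponders with grating responses
    are clustered in step 4; cells never probed with the chirp are assigned
    to existing clusters in step 5. Cells failing every gate are dropped.
    """
    assignments: dict[str, ClusterAssignment] = {}
    counts = {f"step{i}": 0 for i in range(1, 6)}
    counts["dropped"] = 0
    counts["unassigned"] = 0

    chirp_resp = [r for r in records if r.chirp_probed and r.responds_to_chirp]
    chirp_silent = [r for r in records if r.chirp_probed and not r.responds_to_chirp]
    not_probed = [r for r in records if not r.chirp_probed]

    # --- step 1
    step1_hits: list[tuple[CellRecord, int]] = []
    pending_step3: list[CellRecord] = []
    flashless: list[CellRecord] = []
    for r in chirp_resp:
        has_flash = r.flash_polarity not in (None, "none")
        if has_flash and r.chirp_spectrum is not None:
            c = assign_step1(r.profile, r.chirp_spectrum)
            if c is not None:
                assignments[r.unit_id] = ClusterAssignment(r.unit_id, c, 1)
                counts["step1"] += 1
                step1_hits.append((r, c))
            else:
                pending_step3.append(r)
        elif has_flash:
            pending_step3.append(r)
        else:
            flashless.append(r)

    # --- step 2
    populate_template_stats(library, step1_hits)
    for r in flashless:
        c, sim = assign_step2(r, library)
        if c is not None:
            assignments[r.unit_id] = ClusterAssignment(r.unit_id, c, 2, sim)
            counts["step2"] += 1
        else:
            pending_step3.append(r)

    # --- step 3
    for r in pending_step3:
        c, note = group_step3(r)
        assignments[r.unit_id] = ClusterAssignment(r.unit_id, c, 3, note=note)
        counts["step3"] += 1

    # --- step 4
    kmodel: Optional[KMeansModel] = None
    step4_records = [r for r in chirp_silent if r.responds_to_gratings]
    for r in chirp_silent:
        if not r.responds_to_gratings:
            assignments[r.unit_id] = ClusterAssignment(r.unit_id, None, None, note="dropped")
            counts["dropped"] += 1
    if len(step4_records) >= k_range[0] + 1:
        kmodel = cluster_step4([r.grating_map.vector() for r in step4_records],
                               seed=seed, k_range=k_range, repetitions=repetitions)
        for r, lab in zip(step4_records, kmodel.labels):
            assignments[r.unit_id] = ClusterAssignment(r.unit_id, int(lab) + 9, 4)
            counts["step4"] += 1
    else:
        for r in step4_records:
            assignments[r.unit_id] = ClusterAssignment(r.unit_id, None, None, note="dropped")
            counts["dropped"] += 1

    # --- step 5
    cluster_members: dict[int, list[np.ndarray]] = {}
    for r in records:
        asg = assignments.get(r.unit_id)
        if asg is not None and asg.cluster is not None and r.responds_to_gratings:
            cluster_members.setdefault(asg.cluster, []).append(r.grating_map.vector())
    cluster_means = {c: np.mean(v, axis=0) for c, v in cluster_members.items()}
    member_sims = {
        c: np.array([similarity(v, cluster_means[c]) for v in vs])
        for c, vs in cluster_members.items()
    }
    for r in not_probed:
        if not r.responds_to_gratings:
            assignments[r.unit_id] = ClusterAssignment(r.unit_id, None, None, note="dropped")
            counts["dropped"] += 1
            continue
        c, sim = assign_step5(r.grating_map.vector(), cluster_means, member_sims)
        if c is not None:
            assignments[r.unit_id] = ClusterAssignment(r.unit_id, c, 5, sim)
            counts["step5"] += 1
        else:
            assignments[r.unit_id] = ClusterAssignment(r.unit_id, None, None,
                                                       sim, note="unassigned")
            counts["unassigned"] += 1

    ordered = [assignments[r.unit_id] for r in records if r.unit_id in assignments]
    return PipelineResult(assignments=ordered, step_counts=counts,
                          kmeans=kmodel, library=library)
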