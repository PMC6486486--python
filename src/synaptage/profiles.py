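"""Temporal profile classification, cross-region subtraction and candidate selection.

A temporal profile is the ordered triple of mean normalized abundances
(young, mid, old). Its two step changes ``d1 = mid - young`` and
``d2 = old - mid`` are thresholded into qualitative classes (steady up/down,
late-stage up/down, flat, early change). Proteins behaving identically in both
brain regions cannot explain differential regional vulnerability and are
subtracted; among the remainder, proteins concordant between regions at young
and mid age but sharply divergent at old age are reported as vulnerability
candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable


class ProfileClass(str, Enum):
    steady_up = "steady_up"
    steady_down = "steady_down"
    late_up = "late_up"
    late_down = "late_down"
    early_change = "early_change"
    flat = "flat"


#: classes counted as age-changing (the paper's clusters of interest)
CHANGING_CLASSES = frozenset(
    {ProfileClass.steady_up, ProfileClass.steady_down, ProfileClass.late_up, ProfileClass.late_down}
)


@dataclass(frozen=True)
class ClassParams:
    """Thresholds for profile classification, on the normalized (Arc-Sinh) scale.

    ``step_min`` (default 0.18, roughly ln 1.2) is the minimum |step| that
    counts as a change, matching the pipeline's 1.2-fold differential gate;
    ``flat_max`` (default step_min / 2) is the maximum |step| still counted
    as no change.
    """

    step_min: float = 0.18
    flat_max: float | None = None

    def __post_init__(self) -> None:
        if self.flat_max is None:
            object.__setattr__(self, "flat_max", self.step_min / 2)
        if self.step_min <= 0:
            raise ValueError("step_min must be positive")
        if self.flat_max > self.step_min:
            raise ValueError("flat_max must not exceed step_min")


@dataclass
class TemporalProfile:
    """Ordered mean normalized abundance (young, mid, old) of one protein or cluster."""

    id: str
    region: str
    values: tuple[float, float, float]

    @property
    def d1(self) -> float:
        return self.values[1] - self.values[0]

    @property
    def d2(self) -> float:
        return self.values[2] - self.values[1]


def classify_profile(profile: TemporalProfile, params: ClassParams = ClassParams()) -> ProfileClass:
    """Assign a qualitative temporal class to a three-point profile.

    steady_up: both steps non-decreasing with a real first step and a total
    rise of at least two steps; late_up: flat first step then a real rise;
    flat: both steps inside the flat band; mirrored for the down classes;
    anything else (e.g. an early change that then plateaus or reverses) is
    ``early_change``. Exhaustive and mutually exclusive for
    ``flat_max < step_min``.
    """
    d1, d2 = profile.d1, profile.d2
    rise = profile.values[2] - profile.values[0]
    s, f = params.step_min, params.flat_max
    if d1 >= s and d2 >= 0 and rise >= 2 * s:
        return ProfileClass.steady_up
    if d1 <= -s and d2 <= 0 and rise <= -2 * s:
        return ProfileClass.steady_down
    if abs(d1) <= f and d2 >= s:
        return ProfileClass.late_up
    if abs(d1) <= f and d2 <= -s:
        return ProfileClass.late_down
    if abs(d1) <= f and abs(d2) <= f:
        return ProfileClass.flat
    return ProfileClass.early_change


def protein_profiles(table: AbundanceTable, region: str) -> dict[str, TemporalProfile]:
    """Per-protein temporal profile (per-age replicate means) for one region."""
    means = table.group_means(region)
    return {
        pid: TemporalProfile(id=pid, region=region, values=tuple(float(v) for v in row))
        for pid, row in means.iterrows()
    }


def classify_proteins(
    table: AbundanceTable, region: str, params: ClassParams = ClassParams()
) -> dict[str, ProfileClass]:
    return {
        pid: classify_profile(prof, params) for pid, prof in protein_profiles(table, region).items()
    }


def cluster_mean_profiles(
    clusters, table: AbundanceTable, region: str, include_singletons: bool = False
) -> list[TemporalProfile]:
    """Mean temporal profile of each cluster (mean over member proteins of
    per-age replicate means, normalized scale). Singleton clusters are skipped
    by default; empty clusters are skipped with a warning."""
    means = table.group_means(region)
    out: list[TemporalProfile] = []
    member_lists = clusters.clusters if hasattr(clusters, "clusters") else clusters
    for i, members in enumerate(member_lists):
        members = [m for m in members if m in means.index]
        if not members:
            warnings.warn(f"cluster {i} has no members quantified in {region}", stacklevel=2)
            continue
        if len(members) == 1 and not include_singletons:
            continue
        prof = means.loc[members].mean(axis=0)
        out.append(
            TemporalProfile(id=f"cluster_{i}", region=region, values=tuple(float(v) for v in prof))
        )
    return out


def subtract_analogous(region_a, region_b):
    """Remove proteins with the same directional class in both regions.

    ``region_a`` / ``region_b`` are iterables of ``(protein_id, ProfileClass)``
    pairs (or dicts). Returns ``(unique_a, unique_b, removed)``, a three-way
    partition of the union of protein ids: ``removed`` holds proteins present
    in both regions with an exactly matching class; each ``unique_*`` holds
    the region's remaining proteins.
    """
    a = dict(region_a.items() if hasattr(region_a, "items") else region_a)
    b = dict(region_b.items() if hasattr(region_b, "items") else region_b)
    removed = sorted(p for p in a.keys() & b.keys() if a[p] == b[p])
    unique_a = sorted(p for p in a if p not in removed)
    unique_b = sorted(p for p in b if p not in removed)
    return unique_a, unique_b, removed


@dataclass(frozen=True)
class CandidateParams:
    """Gates for old-age divergence candidates, on the normalized scale.

    Between-region concordance at young and mid is capped at ``concord_max``
    (default 0.18 ~ ln 1.2); divergence at old age must reach ``diverge_min``
    (default 0.36 ~ ln 1.44). With ``require_test`` a Welch t-test on the
    old-age replicates of the two regions must also reject at ``alpha``.
    """

    concord_max: float = 0.18
    diverge_min: float = 0.36
    require_test: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.concord_max < self.diverge_min:
            raise ValueError("concord_max must be smaller than diverge_min")


@dataclass
class CandidateReport:
    """Per-protein cross-region divergence assessment."""

    protein: str
    profile_a: TemporalProfile
    profile_b: TemporalProfile
    class_a: ProfileClass
    class_b: ProfileClass
    delta_young: float
    delta_mid: float
    delta_old: float
    divergence_score: float
    old_age_p: float
    verdict: bool
    gates_failed: list[str] = field(default_factory=list)


def select_candidates(
    proteins,
    table: AbundanceTable,
    params: CandidateParams = CandidateParams(),
    regions: tuple[str, str] | None = None,
    class_params: ClassParams = ClassParams(),
) -> list[CandidateReport]:
    """Select proteins concordant between regions at young/mid but divergent at old age.

    ``delta_age = mean(region_a) - mean(region_b)`` on the normalized scale;
    a candidate needs |delta_young| and |delta_mid| <= concord_max,
    |delta_old| >= diverge_min and (optionally) Welch p <= alpha on the
    old-age replicates. The divergence direction is unsigned: candidates may
    diverge up or down in the vulnerable region. Reports are sorted by
    descending divergence score ``|delta_old| - max(|delta_young|, |delta_mid|)``.
    """
    if regions is None:
        found = table.regions
        if len(found) != 2:
            raise ValueError(f"expected exactly 2 regions, found {found}; pass regions=")
        regions = (found[0], found[1])
    ra, rb = regions
    means_a, means_b = table.group_means(ra), table.group_means(rb)
    profs_a, profs_b = protein_profiles(table, ra), protein_profiles(table, rb)
    reports: list[CandidateReport] = []
    for pid in proteins:
        if pid not in means_a.index:
            warnings.warn(f"protein {pid!r} not quantified in both regions; skipped", stacklevel=2)
            continue
        dy = float(means_a.loc[pid, "young"] - means_b.loc[pid, "young"])
        dm = float(means_a.loc[pid, "mid"] - means_b.loc[pid, "mid"])
        do = float(means_a.loc[pid, "old"] - means_b.loc[pid, "old"])
        old_a = table.replicate_values(ra, "old").loc[pid].to_numpy()
        old_b = table.replicate_values(rb, "old").loc[pid].to_numpy()
        if np.ptp(old_a) == 0 and np.ptp(old_b) == 0:
            p = 1.0 if old_a[0] == old_b[0] else 0.0  # degenerate noiseless replicates
        else:
            p = float(stats.ttest_ind(old_a, old_b, equal_var=False).pvalue)
        failed = []
        if abs(dy) > params.concord_max:
            failed.append("concord_young")
        if abs(dm) > params.concord_max:
            failed.append("concord_mid")
        if abs(do) < params.diverge_min:
            failed.append("diverge_old")
        if params.require_test and p > params.alpha:
            failed.append("old_age_test")
        reports.append(
            CandidateReport(
                protein=pid,
                profile_a=profs_a[pid],
                profile_b=profs_b[pid],
                class_a=classify_profile(profs_a[pid], class_params),
                class_b=classify_profile(profs_b[pid], class_params),
                delta_young=dy,
                delta_mid=dm,
                delta_old=do,
                divergence_score=abs(do) - max(abs(dy), abs(dm)),
                old_age_p=p,
                verdict=not failed,
                gates_failed=failed,
            )
        )
    reports.sort(key=lambda r: (-r.divergence_score, r.protein))
    return reports


def candidates_to_frame(reports: list[CandidateReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "protein_id": r.protein,
                "region_a": r.profile_a.region,
                "region_b": r.profile_b.region,
                "class_a": r.class_a.value,
                "class_b": r.class_b.value,
                "delta_young": r.delta_young,
                "delta_mid": r.delta_mid,
                "delta_old": r.delta_old,
                "divergence_score": r.divergence_score,
                "old_age_p": r.old_age_p,
                "verdict": r.verdict,
                "gates_failed": ",".join(r.gates_failed),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id") if rows else pd.DataFrame()
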