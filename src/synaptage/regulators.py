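"""Upstream-regulator activation scoring over a user-supplied signed network.

Given directed edges (regulator, target, sign) — sign +1 if the regulator
activates the target, -1 if it represses it — and an observed direction of
change (+1 up / -1 down) for each measured protein, each regulator is scored
with the simple activation z-score

    z = (N_consistent - N_inconsistent) / sqrt(N_observed_targets),

where a target is consistent with the "regulator activated" hypothesis when
edge sign x observed direction = +1. z >= 2 predicts activation, z <= -2
inhibition. A hypergeometric tail probability measures how surprising the
overlap between the regulator's targets and the observed set is. The network
is an input: no proprietary interaction knowledge base is bundled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .tables import AbundanceTable


@dataclass
class RegulatorNetwork:
    """Signed directed regulator -> target edges."""

    edges: pd.DataFrame  # columns: regulator, target, sign

    def __post_init__(self) -> None:
        req = {"regulator", "target", "sign"}
        if not req <= set(self.edges.columns):
            raise ValueError(f"network needs columns {sorted(req)}")
        self.edges = self.edges[["regulator", "target", "sign"]].copy()
        self.edges["sign"] = self.edges["sign"].astype(int)
        if not self.edges["sign"].isin([1, -1]).all():
            bad = self.edges.loc[~self.edges["sign"].isin([1, -1]), "sign"].iloc[0]
            raise ValueError(f"edge signs must be +1 or -1, got {bad}")
        dup = self.edges.duplicated(subset=["regulator", "target"])
        if dup.any():
            pair = self.edges.loc[dup, ["regulator", "target"]].iloc[0]
            raise ValueError(f"duplicate edge {tuple(pair)}")

    @classmethod
    def from_edges(cls, edges) -> "RegulatorNetwork":
        return cls(pd.DataFrame(edges, columns=["regulator", "target", "sign"]))

    @classmethod
    def from_tsv(cls, path) -> "RegulatorNetwork":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())


@dataclass
class RegulatorScore:
    regulator: str
    n_targets: int  # targets of the regulator in the network
    n_observed: int  # targets with an observed direction
    z: float
    overlap_p: float
    state: str  # activated / inhibited / undetermined


def activation_zscore(
    network: RegulatorNetwork,
    observed: dict,
    universe_size: int,
    z_activated: float = 2.0,
) -> list[RegulatorScore]:
    """Score every regulator with at least one observed target.

    ``observed`` maps protein id -> direction in {+1, -1} (e.g. the sign of
    old-age minus young mean in the contrast region); ``universe_size`` is
    the number of proteins that could have been observed. Results are sorted
    by descending z. |z| is bounded by sqrt(n_observed).
    """
    if not observed:
        raise ValueError("observed direction map is empty")
    if universe_size < len(observed):
        raise ValueError("universe_size must be >= number of observed proteins")
    bad = [p for p, d in observed.items() if d not in (1, -1)]
    if bad:
        raise ValueError(f"observed directions must be +1/-1; bad: {bad[:3]}")
    out = []
    for reg, sub in network.edges.groupby("regulator", sort=True):
        hits = sub[sub["target"].isin(observed)]
        k = len(hits)
        if k == 0:
            warnings.warn(f"regulator {reg!r} has no observed targets; omitted", stacklevel=2)
            continue
        consistent = int((hits["sign"] * hits["target"].map(observed) == 1).sum())
        z = (2 * consistent - k) / math.sqrt(k)
        p = float(stats.hypergeom.sf(k - 1, universe_size, len(sub), len(observed)))
        state = (
            "activated" if z >= z_activated else "inhibited" if z <= -z_activated else "undetermined"
        )
        out.append(
            RegulatorScore(
                regulator=str(reg), n_targets=len(sub), n_observed=k, z=float(z),
                overlap_p=p, state=state,
            )
        )
    out.sort(key=lambda s: (-s.z, s.regulator))
    return out


def observed_directions(table: AbundanceTable, region: str, proteins=None) -> dict:
    """Direction of change at old age vs young (sign of old - young mean) per protein.

    Proteins with exactly equal means are omitted (no direction).
    """
    means = table.group_means(region)
    if proteins is not None:
        means = means.loc[[p for p in proteins if p in means.index]]
    delta = means["old"] - means["young"]
    return {pid: (1 if d > 0 else -1) for pid, d in delta.items() if d != 0}


def scores_to_frame(scores: list[RegulatorScore]) -> pd.DataFrame:
    if not scores:
        return pd.DataFrame(
            columns=["regulator", "n_targets", "n_observed", "z", "overlap_p", "state"]
        ).set_index("regulator")
    return pd.DataFrame([vars(s) for s in scores]).set_index("regulator")
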