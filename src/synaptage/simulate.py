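"""Synthetic abundance tables with planted ground truth.

The generator emulates the design of a pooled-sample regional aging time
course: two brain regions (vulnerable and resistant), three ordered age groups
and a small number of technical replicates of each pooled sample, measured as
label-free MS intensities. Each protein carries a planted temporal profile
class (steady up/down over the time course, late-stage up/down, or flat);
planted divergence candidates behave identically in both regions at young and
mid age and split between regions at old age; an optional signed
regulator -> target edge set is planted for activation scoring.

Because samples are pooled per (region, age) before measurement, only
multiplicative technical replicate noise is modelled: each replicate value is
the expected group mean times a mean-one log-normal factor whose coefficient
of variation is ``replicate_cv`` (sigma = sqrt(ln(1 + CV^2)) on the log
scale). Intensities are right-skewed, so baseline abundances are log-normal
across proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import ProfileClass
from .tables import AbundanceTable


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


#: classes the generator can plant (early_change never planted directly)
PLANTABLE = (
    ProfileClass.steady_up,
    ProfileClass.steady_down,
    ProfileClass.late_up,
    ProfileClass.late_down,
    ProfileClass.flat,
)

DEFAULT_FRACTIONS = {
    ProfileClass.steady_up: 0.125,
    ProfileClass.steady_down: 0.125,
    ProfileClass.late_up: 0.125,
    ProfileClass.late_down: 0.125,
    ProfileClass.flat: 0.5,
}


@dataclass(frozen=True)
class RegulatorSpec:
    """One planted regulator: id, number of targets, and edge sign pattern.

    ``signs`` is a string over ``+``/``-`` cycled to ``n_targets``. With
    ``coherent=True`` the regulator is planted as *activated* in the
    vulnerable region: ``+`` edges point at proteins moving up at old age and
    ``-`` edges at proteins moving down. With ``coherent=False`` targets are
    drawn at random (a decoy regulator).
    """

    regulator: str
    n_targets: int
    signs: str = "+"
    coherent: bool = True

    def sign_list(self) -> list[int]:
        if not self.signs or any(c not in "+-" for c in self.signs):
            raise ConfigError(f"regulator_spec.signs must be over '+-', got {self.signs!r}")
        return [1 if self.signs[i % len(self.signs)] == "+" else -1 for i in range(self.n_targets)]


@dataclass
class SimConfig:
    """Parameters of the synthetic regional aging time course."""

    n_proteins: int = 500
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    base_abundance_logmean: float = 8.0
    base_abundance_logsd: float = 1.0
    effect_fc: float = 1.5
    replicate_cv: float = 0.10
    n_replicates: int = 3
    n_candidates: int = 20
    candidate_divergence_fc: float = 2.0
    seed: int = 0
    regulator_spec: list[RegulatorSpec] = field(default_factory=list)
    regions: tuple[str, str] = ("HC", "OCC")  # vulnerable first
    ages: tuple[str, str, str] = ("young", "mid", "old")
    peptide_rate: float = 3.0  # unique peptides ~ 1 + Poisson(rate)

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigError("n_proteins must be positive")
        fracs = {ProfileClass(k): float(v) for k, v in self.class_fractions.items()}
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ConfigError("class_fractions must sum to 1 within 1e-9")
        if any(v < 0 for v in fracs.values()):
            raise ConfigError("class_fractions must be nonnegative")
        if self.effect_fc <= 1:
            raise ConfigError("effect_fc must be > 1")
        if self.candidate_divergence_fc <= 1:
            raise ConfigError("candidate_divergence_fc must be > 1")
        if self.replicate_cv < 0:
            raise ConfigError("replicate_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0 <= self.n_candidates <= self.n_proteins:
            raise ConfigError("n_candidates must lie in [0, n_proteins]")
        if self.base_abundance_logsd <= 0:
            raise ConfigError("base_abundance_logsd must be positive")
        if len(self.regions) != 2:
            raise ConfigError("regions must name exactly two regions")


@dataclass
class TruthRecord:
    classes: dict  # region -> ProfileClass
    is_candidate: bool
    regulators: tuple = ()  # ((regulator_id, sign), ...)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per protein, the profile class in each region,
    the candidate flag and regulator memberships; plus (non-serialized) the
    regulator edge list and noiseless expected group means."""

    records: dict  # protein id -> TruthRecord
    network: list = field(default_factory=list, compare=False)  # (reg, target, sign)
    expected_means: dict = field(default_factory=dict, compare=False)  # region -> DataFrame

    def candidates(self) -> list[str]:
        return sorted(p for p, r in self.records.items() if r.is_candidate)

    def classes(self, region: str) -> dict:
        return {p: r.classes[region] for p, r in self.records.items()}


def _class_multipliers(cls: ProfileClass, f: float) -> np.ndarray:
    if cls is ProfileClass.steady_up:
        return np.array([1.0, f, f * f])
    if cls is ProfileClass.steady_down:
        return np.array([1.0, 1 / f, 1 / (f * f)])
    if cls is ProfileClass.late_up:
        return np.array([1.0, 1.0, f * f])
    if cls is ProfileClass.late_down:
        return np.array([1.0, 1.0, 1 / (f * f)])
    return np.array([1.0, 1.0, 1.0])


def _class_counts(cfg: SimConfig) -> dict:
    """Largest-remainder apportionment of n_proteins over class_fractions."""
    fracs = {ProfileClass(k): float(v) for k, v in cfg.class_fractions.items()}
    raw = {c: cfg.n_proteins * fracs.get(c, 0.0) for c in PLANTABLE}
    counts = {c: math.floor(v) for c, v in raw.items()}
    short = cfg.n_proteins - sum(counts.values())
    for c in sorted(PLANTABLE, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _label_from_multipliers(mult: np.ndarray) -> ProfileClass:
    """Truth class implied by a noiseless multiplier profile (log-scale steps)."""
    lo = np.log(mult)
    d1, d2 = lo[1] - lo[0], lo[2] - lo[1]
    eps = 1e-12
    if d1 > eps and d2 >= -eps:
        return ProfileClass.steady_up
    if d1 < -eps and d2 <= eps:
        return ProfileClass.steady_down
    if abs(d1) <= eps and d2 > eps:
        return ProfileClass.late_up
    if abs(d1) <= eps and d2 < -eps:
        return ProfileClass.late_down
    if abs(d1) <= eps and abs(d2) <= eps:
        return ProfileClass.flat
    return ProfileClass.early_change


def simulate_dataset(cfg: SimConfig) -> tuple[AbundanceTable, SyntheticTruth]:
    """Generate an abundance table and its planted truth. Deterministic given seed.

    Expected group means: a protein of class steady_up has means mu, mu*f,
    mu*f^2 across the age groups (f = effect_fc); late_up has mu, mu, mu*f^2;
    the down classes are reciprocal; flat is constant. Divergence candidates
    are planted on flat backgrounds: identical in both regions at young and
    mid, with the vulnerable region's old-age mean multiplied (or divided,
    direction drawn at random) by candidate_divergence_fc, so the divergence
    is the only age signal they carry.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    width = max(4, len(str(n)))
    proteins = [f"P{i:0{width}d}" for i in range(1, n + 1)]

    counts = _class_counts(cfg)
    if cfg.n_candidates > counts[ProfileClass.flat]:
        raise ConfigError(
            "n_candidates exceeds the number of flat-class proteins "
            f"({cfg.n_candidates} > {counts[ProfileClass.flat]}); candidates are planted on flat backgrounds"
        )
    labels = np.array(
        [c for c in PLANTABLE for _ in range(counts[c])], dtype=object
    )
    rng.shuffle(labels)

    flat_idx = np.array([i for i, lab in enumerate(labels) if lab is ProfileClass.flat], dtype=int)
    cand_idx = rng.choice(flat_idx, size=cfg.n_candidates, replace=False)
    cand_dir = rng.choice([1.0, -1.0], size=cfg.n_candidates)

    base = rng.lognormal(cfg.base_abundance_logmean, cfg.base_abundance_logsd, size=n)
    peptides = 1 + rng.poisson(cfg.peptide_rate, size=n)

    # expected means per region (proteins x 3 ages)
    mult = {r: np.empty((n, 3)) for r in cfg.regions}
    for i, lab in enumerate(labels):
        m = _class_multipliers(lab, cfg.effect_fc)
        for r in cfg.regions:
            mult[r][i] = m
    vuln = cfg.regions[0]
    for j, i in enumerate(cand_idx):
        mult[vuln][i, 2] *= cfg.candidate_divergence_fc ** cand_dir[j]

    sigma = math.sqrt(math.log1p(cfg.replicate_cv**2))
    columns, data = [], []
    for r in cfg.regions:
        for a_ix, age in enumerate(cfg.ages):
            expected = base * mult[r][:, a_ix]
            for rep in range(1, cfg.n_replicates + 1):
                if sigma > 0:
                    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n)
                else:
                    noise = 1.0
                columns.append(f"{r}_{age}_{rep}")
                data.append(expected * noise)
    values = pd.DataFrame(np.column_stack(data), index=proteins, columns=columns)
    samples = pd.DataFrame(
        [(c, *c.rsplit("_", 2)) for c in columns],
        columns=["sample", "region", "age", "replicate"],
    ).set_index("sample")
    table = AbundanceTable(
        values=values,
        samples=samples,
        unique_peptides=pd.Series(peptides, index=proteins, name="unique_peptides"),
        normalized=False,
    )

    records = {}
    for i, pid in enumerate(proteins):
        records[pid] = TruthRecord(
            classes={r: _label_from_multipliers(mult[r][i]) for r in cfg.regions},
            is_candidate=False,
        )
    for i in cand_idx:
        records[proteins[i]].is_candidate = True

    network = _plant_regulators(cfg, rng, proteins, records)
    reg_of: dict[str, list] = {p: [] for p in proteins}
    for reg, tgt, sign in network:
        reg_of[tgt].append((reg, sign))
    for pid in proteins:
        records[pid].regulators = tuple(reg_of[pid])

    expected = {
        r: pd.DataFrame(base[:, None] * mult[r], index=proteins, columns=list(cfg.ages))
        for r in cfg.regions
    }
    return table, SyntheticTruth(records=records, network=network, expected_means=expected)


def _plant_regulators(cfg: SimConfig, rng, proteins, records) -> list:
    """Draw regulator -> target edges; coherent regulators get sign-matched targets."""
    vuln = cfg.regions[0]
    up_pool, down_pool = [], []
    for pid in proteins:
        cls = records[pid].classes[vuln]
        if cls in (ProfileClass.steady_up, ProfileClass.late_up):
            up_pool.append(pid)
        elif cls in (ProfileClass.steady_down, ProfileClass.late_down):
            down_pool.append(pid)
    network = []
    for spec in cfg.regulator_spec:
        signs = spec.sign_list()
        if spec.coherent:
            n_up = sum(1 for s in signs if s == 1)
            n_down = len(signs) - n_up
            if n_up > len(up_pool) or n_down > len(down_pool):
                raise ConfigError(
                    f"regulator {spec.regulator!r} needs {n_up} up / {n_down} down targets; "
                    f"pools have {len(up_pool)} / {len(down_pool)}"
                )
            ups = list(rng.choice(up_pool, size=n_up, replace=False))
            downs = list(rng.choice(down_pool, size=n_down, replace=False))
            for s in signs:
                network.append((spec.regulator, ups.pop() if s == 1 else downs.pop(), s))
        else:
            targets = rng.choice(proteins, size=spec.n_targets, replace=False)
            for tgt, s in zip(targets, signs):
                network.append((spec.regulator, str(tgt), s))
    return network


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write truth as TSV: one row per (protein, region) with class, candidate
    flag and ``reg:sign`` memberships."""
    if not truth.records:
        raise ValueError("truth is empty")
    rows = []
    for pid in sorted(truth.records):
        rec = truth.records[pid]
        regs = ";".join(f"{r}:{s:+d}" for r, s in rec.regulators)
        for region, cls in rec.classes.items():
            rows.append((pid, region, cls.value, rec.is_candidate, regs))
    pd.DataFrame(
        rows, columns=["protein_id", "region", "class", "is_candidate", "regulators"]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records: dict[str, TruthRecord] = {}
    network = []
    seen_regs = set()
    for _, row in df.iterrows():
        pid = row["protein_id"]
        rec = records.setdefault(pid, TruthRecord(classes={}, is_candidate=bool(row["is_candidate"])))
        rec.classes[row["region"]] = ProfileClass(row["class"])
        if row["regulators"] and pid not in seen_regs:
            seen_regs.add(pid)
            regs = []
            for item in str(row["regulators"]).split(";"):
                reg, sign = item.rsplit(":", 1)
                regs.append((reg, int(sign)))
                network.append((reg, pid, int(sign)))
            rec.regulators = tuple(regs)
    return SyntheticTruth(records=records, network=network)
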