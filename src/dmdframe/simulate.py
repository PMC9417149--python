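"""Synthetic dystrophinopathy cohorts.

Real per-patient data behind this kind of genotype-phenotype study are
rarely released; this module generates cohorts with the same statistical
skeleton so the whole pipeline is testable end to end.

Two generators are provided:

* :func:`simulate_cohort` — a stochastic cohort: phenotype is Bernoulli,
  frame-status concordance with phenotype follows configurable conditional
  probabilities (realised by sampling an exon range whose mod-3 residue
  matches the drawn status, so the frame arithmetic and the sampler can
  never disagree), and the continuous clinical variables (walking-alone
  milestone, onset age, diagnosis age, CK, age at ambulation loss) are
  truncated normals with the published summary moments as defaults.
* :func:`fixture_cohort` — the deterministic 169-patient reconstruction of
  the study cohort: the unique integer frame x milestone x phenotype table
  consistent with every published marginal count, with continuous fields
  held at representative mid-range values (the rule evaluations depend
  only on the discrete cells).

Exon ranges are drawn from a hotspot mixture (mass on the distal 44-55 and
proximal 3-26 deletion hotspots, a remainder spread over the whole
interior) with a geometric exon-count distribution, then resolved exactly:
all interior ranges are enumerated once, partitioned by frame class, and
sampled with the mixture weights renormalised within the class.  This is
distributionally identical to rejection sampling against the frame target
but cannot stall; an empty class raises :class:`SimulationError`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .classify import POINT_MUTATION, PatientRecord
from .gene_model import (
    N_EXONS,
    ExonTable,
    FrameStatus,
    VariantEvent,
    VariantKind,
    coding_span_length,
    load_exon_table,
)

__all__ = [
    "CohortSimParams",
    "SimulationError",
    "TruncNormal",
    "fixture_cohort",
    "fixture_manifest",
    "simulate_cohort",
]


class SimulationError(RuntimeError):
    """Raised when the requested cohort structure cannot be realised."""


@dataclass(frozen=True)
class TruncNormal:
    """A normal distribution truncated to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.low >= self.high:
            raise ValueError("truncation bounds must be ordered low < high")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class HotspotRegion:
    start_exon: int
    end_exon: int
    weight: float


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort generator settings; defaults emulate the study conditions.

    Proportions: 152/169 DMD prevalence in an ascertained del/dup cohort;
    frame-rule concordance 86.8% in DMD and 70.6% in BMD; duplications at
    the cohort rate 16/169 (assigned to DMD cases only — the study saw no
    BMD duplication).  Continuous variables carry the published group
    means, SDs and ranges: walking-alone milestone in months, onset /
    diagnosis / ambulation-loss ages in years, CK in U/L.
    """

    n_patients: int = 169
    seed: int = 0
    p_dmd: float = 152 / 169
    p_out_of_frame_given_dmd: float = 0.868
    p_in_frame_given_bmd: float = 0.706
    p_duplication: float = 16 / 169
    milestone_dmd: TruncNormal = TruncNormal(18.03, 7.12, 14.0, 30.0)
    milestone_bmd: TruncNormal = TruncNormal(12.88, 0.61, 12.0, 14.0)
    onset_dmd: TruncNormal = TruncNormal(3.9, 2.18, 0.5, 9.0)
    onset_bmd: TruncNormal = TruncNormal(6.49, 3.06, 2.8, 12.0)
    diagnosis_dmd: TruncNormal = TruncNormal(6.8, 2.83, 1.27, 14.34)
    diagnosis_bmd: TruncNormal = TruncNormal(7.16, 3.45, 2.8, 12.0)
    ck_dmd: TruncNormal = TruncNormal(16197.2, 8750.9, 4463.0, 57296.0)
    ck_bmd: TruncNormal = TruncNormal(8657.5, 5933.3, 1199.0, 20048.6)
    ambulation_loss_dmd: TruncNormal = TruncNormal(11.14, 1.07, 8.0, 14.0)
    followup_bmd_range: tuple[float, float] = (16.0, 18.0)
    hotspots: tuple[HotspotRegion, ...] = (
        HotspotRegion(44, 55, 0.55),
        HotspotRegion(3, 26, 0.33),
    )
    p_single_exon: float = 0.28  # geometric exon-count parameter
    lognormal_ck: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("p_dmd", "p_out_of_frame_given_dmd", "p_in_frame_given_bmd", "p_duplication"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.p_single_exon < 1.0:
            raise ValueError("p_single_exon must be in (0, 1)")
        total_hotspot = sum(h.weight for h in self.hotspots)
        if total_hotspot > 1.0 + 1e-9:
            raise ValueError("hotspot weights must sum to at most 1")


class _RangeSampler:
    """Exact sampler of interior exon ranges conditioned on frame class.

    Weight of range (a, b): hotspot-mixture mass of any region containing
    it (plus the whole-interior remainder component) times a geometric pmf
    on the exon count.  Ranges are pre-partitioned into frame-preserving
    and frame-shifting classes using the exon table, so every draw is a
    single categorical sample.
    """

    def __init__(self, table: ExonTable, params: CohortSimParams) -> None:
        starts, ends = [], []
        for a in range(2, N_EXONS):
            for b in range(a, N_EXONS):
                starts.append(a)
                ends.append(b)
        starts = np.array(starts)
        ends = np.array(ends)
        n_exon = ends - starts + 1
        p = params.p_single_exon
        length_pmf = p * (1.0 - p) ** (n_exon - 1)

        remainder = 1.0 - sum(h.weight for h in params.hotspots)
        region_mass = np.full(starts.shape, remainder, dtype=float)
        for h in params.hotspots:
            inside = (starts >= h.start_exon) & (ends <= h.end_exon)
            region_mass[inside] += h.weight
        weights = region_mass * length_pmf

        cumulative = np.concatenate([[0], np.cumsum(table.lengths)])
        residue = (cumulative[ends] - cumulative[starts - 1]) % 3
        in_frame = residue == 0

        self._pools: dict[bool, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for flag in (True, False):
            mask = in_frame if flag else ~in_frame
            w = weights[mask]
            if w.sum() <= 0:
                raise SimulationError(
                    "no exon range available for frame class "
                    f"{'in_frame' if flag else 'out_of_frame'}"
                )
            self._pools[flag] = (starts[mask], ends[mask], w / w.sum())

    def draw(self, rng: np.random.Generator, in_frame: bool, size: int) -> tuple[np.ndarray, np.ndarray]:
        starts, ends, probs = self._pools[in_frame]
        idx = rng.choice(starts.size, size=size, p=probs)
        return starts[idx], ends[idx]


def simulate_cohort(
    params: CohortSimParams | None = None,
    table: ExonTable | None = None,
) -> list[PatientRecord]:
    """Draw a synthetic cohort; the same seed yields the identical cohort."""
    params = params or CohortSimParams()
    table = table or load_exon_table()
    rng = np.random.default_rng(params.seed)
    sampler = _RangeSampler(table, params)
    n = params.n_patients

    is_dmd = rng.random(n) < params.p_dmd
    out_of_frame = np.where(
        is_dmd,
        rng.random(n) < params.p_out_of_frame_given_dmd,
        rng.random(n) >= params.p_in_frame_given_bmd,
    )
    is_dup = is_dmd & (rng.random(n) < params.p_duplication)

    starts = np.zeros(n, dtype=int)
    ends = np.zeros(n, dtype=int)
    for flag in (True, False):
        mask = out_of_frame != flag  # flag True -> in-frame patients
        if mask.any():
            starts[mask], ends[mask] = sampler.draw(rng, flag, int(mask.sum()))

    def by_group(dmd_dist: TruncNormal, bmd_dist: TruncNormal) -> np.ndarray:
        values = np.empty(n)
        n_dmd = int(is_dmd.sum())
        if n_dmd:
            values[is_dmd] = dmd_dist.sample(rng, n_dmd)
        if n - n_dmd:
            values[~is_dmd] = bmd_dist.sample(rng, n - n_dmd)
        return values

    milestone = by_group(params.milestone_dmd, params.milestone_bmd)
    onset = by_group(params.onset_dmd, params.onset_bmd)
    diagnosis = by_group(params.diagnosis_dmd, params.diagnosis_bmd)
    if params.lognormal_ck:
        ck = np.empty(n)
        for mask, dist in ((is_dmd, params.ck_dmd), (~is_dmd, params.ck_bmd)):
            if mask.any():
                sigma2 = np.log1p(dist.sd**2 / dist.mean**2)
                mu = np.log(dist.mean) - sigma2 / 2.0
                ck[mask] = rng.lognormal(mu, np.sqrt(sigma2), int(mask.sum()))
    else:
        ck = by_group(params.ck_dmd, params.ck_bmd)

    loss_age = params.ambulation_loss_dmd.sample(rng, n)
    lo, hi = params.followup_bmd_range
    followup_bmd = rng.uniform(lo, hi, n)

    records = []
    for i in range(n):
        kind = VariantKind.DUPLICATION if is_dup[i] else VariantKind.DELETION
        variant = VariantEvent(kind=kind, start_exon=int(starts[i]), end_exon=int(ends[i]))
        if is_dmd[i]:
            lost, age_loss = True, round(float(loss_age[i]), 2)
            last = age_loss + 1.0
        else:
            lost, age_loss = False, None
            last = round(float(followup_bmd[i]), 2)
        records.append(
            PatientRecord(
                patient_id=f"sim{i:06d}",
                sex="male",
                variant=variant,
                first_walking_age_months=round(float(milestone[i]), 2),
                onset_age_years=round(float(onset[i]), 2),
                diagnosis_age_years=round(float(diagnosis[i]), 2),
                ck_u_per_l=round(float(ck[i]), 1),
                ambulation_lost=lost,
                age_at_ambulation_loss_years=age_loss,
                age_at_last_followup_years=last,
            )
        )
    return records


# Deterministic reconstruction of the 169-patient study cohort.  The joint
# frame x milestone x phenotype cell counts are the unique non-negative
# integer table consistent with all published marginals: 152 DMD (132
# out-of-frame, 20 in-frame; 93 with a delayed milestone, of whom 14 are
# in-frame) and 17 BMD (12 in-frame, 5 out-of-frame, none delayed).  The 16
# duplications sit in the out-of-frame DMD cell (all study duplications
# were DMD).
_DEL_OUT = ("del", 45, 45)       # 176 nt, frame-shifting
_DUP_OUT = ("dup", 52, 52)       # 118 nt, frame-shifting
_DEL_IN = ("del", 45, 47)        # 474 nt, frame-preserving
_FIXTURE_CELLS: tuple[tuple[str, tuple, int, bool, int], ...] = (
    # (phenotype, variant, count, delayed, walking age months)
    ("DMD", _DEL_OUT, 79, True, 22.0),
    ("DMD", _DEL_OUT, 37, False, 16.0),
    ("DMD", _DUP_OUT, 16, False, 16.0),
    ("DMD", _DEL_IN, 14, True, 22.0),
    ("DMD", _DEL_IN, 6, False, 16.0),
    ("BMD", _DEL_IN, 12, False, 13.0),
    ("BMD", _DEL_OUT, 5, False, 13.0),
)


def _make_record(
    pid: str,
    phenotype: str,
    variant_spec: tuple | str,
    walking_months: float,
) -> PatientRecord:
    if variant_spec == POINT_MUTATION:
        variant: VariantEvent | str = POINT_MUTATION
    else:
        kind, a, b = variant_spec
        variant = VariantEvent(
            kind=VariantKind.DELETION if kind == "del" else VariantKind.DUPLICATION,
            start_exon=a,
            end_exon=b,
        )
    if phenotype == "DMD":
        return PatientRecord(
            patient_id=pid,
            sex="male",
            variant=variant,
            first_walking_age_months=walking_months,
            onset_age_years=3.9,
            diagnosis_age_years=6.8,
            ck_u_per_l=16197.2,
            ambulation_lost=True,
            age_at_ambulation_loss_years=11.14,
            age_at_last_followup_years=12.5,
        )
    if phenotype == "BMD":
        return PatientRecord(
            patient_id=pid,
            sex="male",
            variant=variant,
            first_walking_age_months=walking_months,
            onset_age_years=6.49,
            diagnosis_age_years=7.16,
            ck_u_per_l=8657.5,
            ambulation_lost=False,
            age_at_ambulation_loss_years=None,
            age_at_last_followup_years=17.0,
        )
    # still ambulant, under the classification cutoff
    return PatientRecord(
        patient_id=pid,
        sex="male",
        variant=variant,
        first_walking_age_months=walking_months,
        onset_age_years=3.9,
        diagnosis_age_years=6.8,
        ck_u_per_l=16197.2,
        ambulation_lost=False,
        age_at_ambulation_loss_years=None,
        age_at_last_followup_years=10.0,
    )


def fixture_cohort() -> list[PatientRecord]:
    """The deterministic 169-patient reconstructed cohort (see module docs).

    Continuous fields carry group-representative values; only the discrete
    frame / milestone / phenotype cells matter for rule evaluation.
    """
    records = []
    i = 0
    for phenotype, variant_spec, count, _delayed, months in _FIXTURE_CELLS:
        for _ in range(count):
            i += 1
            records.append(_make_record(f"fx{i:03d}", phenotype, variant_spec, months))
    return records


def fixture_manifest() -> list[PatientRecord]:
    """The 208-registration study-profile manifest: the 169 eligible
    reconstructed patients, 23 point-mutation cases, and 16 still-ambulant
    patients under the 16-year classification cutoff."""
    records = fixture_cohort()
    for j in range(23):
        records.append(
            _make_record(f"pm{j + 1:02d}", "DMD", POINT_MUTATION, 20.0)
        )
    for j in range(16):
        records.append(
            _make_record(f"ya{j + 1:02d}", "ambulant_young", ("del", 45, 45), 17.0)
        )
    return records


def params_as_dict(params: CohortSimParams) -> dict:
    """Plain-dict view of simulation parameters (for YAML sidecars)."""
    return asdict(params)
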