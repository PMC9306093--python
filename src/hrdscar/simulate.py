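"""Synthetic data generators: scar-bearing profiles, SNP emissions,
purity-dilution series, and clinical cohorts with survival endpoints.

These generators stand in for patient-level data that are not publicly
deposited.  Each planted scar event is isolated by 4 Mb uncovered gaps
(wider than the 3 Mb continuity limit) so that it contributes to exactly one
scar count: an interstitial LOH run with zero-gap diploid neighbours would
otherwise also create two large-scale state transitions.  An uncovered gap
can only appear wider when observed through randomly placed SNPs, so the
isolation survives the SNP round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele import expected_baf_logr
from .genome import GenomeBuild, Segment, SegmentProfile
from .scars import ScarScores

__all__ = [
    "ScarEventSpec",
    "CohortSpec",
    "simulate_profile",
    "emit_snps",
    "dilution_series",
    "simulate_cohort",
    "hrd_positive_preset",
    "DEFAULT_DILUTION_PURITIES",
    "DEFAULT_NOISE_SD",
]

# signal-level stand-in for ~500X panel sequencing noise
DEFAULT_NOISE_SD: tuple[float, float] = (0.03, 0.10)
DEFAULT_DILUTION_PURITIES: tuple[float, ...] = (0.50, 0.40, 0.30, 0.20, 0.10, 0.05, 0.0)

_EVENT_GAP = 4_000_000  # uncovered gap isolating planted events (> merge_max_gap)
_ARM_MARGIN = 3_000_000  # planted events keep this far from the centromere end


class InfeasibleSpecError(ValueError):
    """Raised when the requested events cannot be placed on the genome."""


@dataclass(frozen=True)
class ScarEventSpec:
    """Ground-truth event counts for a simulated tumor profile."""

    n_loh_events: int = 0
    n_tai_events: int = 0
    n_lst_events: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_loh_events, self.n_tai_events, self.n_lst_events) < 0:
            raise ValueError("event counts must be >= 0")


def hrd_positive_preset(seed: int = 0) -> ScarEventSpec:
    """A heavily scarred, HRD-positive tumor profile (synthetic stand-in for a
    genomically unstable triple-negative breast-cancer cell line)."""
    return ScarEventSpec(n_loh_events=12, n_tai_events=8, n_lst_events=15, seed=seed)


@dataclass
class _ArmLayout:
    chromosome: str
    arm_start: int
    arm_end: int
    telomere_at_start: bool  # p arm: telomere at arm_start; q arm: at arm_end
    used: int = 0
    has_tai: bool = False
    items: list = field(default_factory=list)  # (kind, run_len, spacer_len)

    @property
    def capacity(self) -> int:
        return self.arm_end - self.arm_start - _ARM_MARGIN

    def fits(self, need: int) -> bool:
        return self.used + need <= self.capacity


def _draw_event(kind: str, rng: np.random.Generator) -> tuple[int, int]:
    """Return (run_length, spacer_length) in bp for one event."""
    mb = 1_000_000
    if kind == "loh":
        run = int(rng.uniform(16, 30) * mb)
        spacer = int(rng.uniform(12, 18) * mb)
    elif kind == "tai":
        run = int(rng.uniform(12, 20) * mb)
        spacer = 0
    elif kind == "lst":
        run = int(rng.uniform(12, 18) * mb)
        spacer = int(rng.uniform(12, 18) * mb)
    else:  # pragma: no cover
        raise ValueError(kind)
    return run, spacer


def _event_need(kind: str, run: int, spacer: int) -> int:
    if kind == "loh":
        return spacer + _EVENT_GAP + run + _EVENT_GAP
    if kind == "tai":
        return run + _EVENT_GAP
    return spacer + run + _EVENT_GAP  # lst


def simulate_profile(
    genome: GenomeBuild, spec: ScarEventSpec
) -> tuple[SegmentProfile, ScarScores]:
    """Plant scar events on a diploid background and return the ground truth.

    Events per arm are laid out from the telomere inward:

    * TAI — a telomere-anchored (2,1) run of 12-20 Mb followed by a gap
      (at most one per arm);
    * LOH — a gap-isolated interstitial (1,0) run of 16-30 Mb;
    * LST — a >=12 Mb neutral spacer directly abutting a (2,1) run of
      12-18 Mb (one state transition), followed by a gap.

    The remainder of every arm is copy-neutral diploid (1,1).  Event
    placement, lengths, and arm assignment are reproducible under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    arms: list[_ArmLayout] = []
    for chrom in genome:
        arms.append(_ArmLayout(chrom.name, *chrom.p_arm, telomere_at_start=True))
        arms.append(_ArmLayout(chrom.name, *chrom.q_arm, telomere_at_start=False))

    events = (
        ["tai"] * spec.n_tai_events
        + ["loh"] * spec.n_loh_events
        + ["lst"] * spec.n_lst_events
    )
    # place telomere-bound TAI events first: they need the front of an arm
    for kind in events:
        run, spacer = _draw_event(kind, rng)
        need = _event_need(kind, run, spacer)
        candidates = [
            a
            for a in arms
            if a.fits(need) and not (kind == "tai" and (a.has_tai or a.items))
        ]
        if not candidates:
            raise InfeasibleSpecError(
                f"cannot place {kind} event of {need} bp: not enough arm space "
                f"for spec {spec}"
            )
        arm = candidates[int(rng.integers(len(candidates)))]
        arm.items.append((kind, run, spacer))
        arm.used += need
        if kind == "tai":
            arm.has_tai = True

    segments: list[Segment] = []
    for arm in arms:
        segments.extend(_lay_out_arm(arm, rng))
    profile = SegmentProfile(sample_id=f"sim-{spec.seed}", segments=tuple(segments))
    profile = replace(profile, ploidy=profile.mean_copy_number())
    hrd = spec.n_loh_events + spec.n_tai_events + spec.n_lst_events
    planted = ScarScores(
        loh_score=spec.n_loh_events,
        tai_score=spec.n_tai_events,
        lst_score=spec.n_lst_events,
        hrd_score=hrd,
        ploidy_used=profile.ploidy,
    )
    return profile, planted


def _lay_out_arm(arm: _ArmLayout, rng: np.random.Generator) -> list[Segment]:
    """Materialize an arm's planted items as segments (offsets from telomere)."""
    pieces: list[tuple[int, int, int, int]] = []  # (offset, length, major, minor)
    pos = 0
    # non-TAI items in shuffled order after the TAI anchor (if any)
    anchor = [it for it in arm.items if it[0] == "tai"]
    interior = [it for it in arm.items if it[0] != "tai"]
    rng.shuffle(interior)
    for kind, run, spacer in anchor + interior:
        if kind == "tai":
            pieces.append((0, run, 2, 1))
            pos = run + _EVENT_GAP
        elif kind == "loh":
            pieces.append((pos, spacer, 1, 1))
            pieces.append((pos + spacer + _EVENT_GAP, run, 1, 0))
            pos += spacer + _EVENT_GAP + run + _EVENT_GAP
        else:  # lst: neutral spacer abuts the run -> exactly one break
            pieces.append((pos, spacer, 1, 1))
            pieces.append((pos + spacer, run, 2, 1))
            pos += spacer + run + _EVENT_GAP
    arm_len = arm.arm_end - arm.arm_start
    if pos < arm_len:
        pieces.append((pos, arm_len - pos, 1, 1))

    segs = []
    for offset, length, major, minor in pieces:
        if arm.telomere_at_start:
            start = arm.arm_start + offset
        else:
            start = arm.arm_end - offset - length
        segs.append(
            Segment(
                chromosome=arm.chromosome,
                start=start,
                end=start + length,
                major_cn=major,
                minor_cn=minor,
            )
        )
    return sorted(segs, key=lambda s: s.start)


def emit_snps(
    profile: SegmentProfile,
    purity: float,
    n_snps: int = 12_000,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    seed: int = 0,
    ploidy: float | None = None,
) -> pd.DataFrame:
    """Emit heterozygous-SNP observations from a profile at a given purity.

    Positions are uniform over the covered genome; observed values are the
    mixture-model expectations plus independent Gaussian noise, with BAF
    clipped to [0, 1].  Germline-site selection is assumed done upstream, so
    every emitted site is heterozygous in the normal.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if ploidy is None:
        ploidy = profile.ploidy if profile.ploidy is not None else profile.mean_copy_number()
    rng = np.random.default_rng(seed)
    segs = profile.segments
    lengths = np.array([s.length for s in segs], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    u = rng.random(n_snps) * cum[-1]
    idx = np.searchsorted(cum, u, side="right") - 1
    offsets = (u - cum[idx]).astype(int)

    sd_baf, sd_logr = noise_sd
    rows = []
    for i, off in zip(idx, offsets):
        s = segs[i]
        baf, logr = expected_baf_logr(s.major_cn, s.minor_cn, purity, ploidy)
        rows.append((s.chromosome, s.start + int(off), baf, logr))
    df = pd.DataFrame(rows, columns=["chromosome", "position", "baf", "logr"])
    df["baf"] = np.clip(df["baf"] + rng.normal(0, sd_baf, n_snps), 0.0, 1.0)
    df["logr"] = df["logr"] + rng.normal(0, sd_logr, n_snps)
    return df.sort_values(["chromosome", "position"], kind="stable").reset_index(
        drop=True
    )


def dilution_series(
    profile: SegmentProfile,
    purities: Sequence[float] = DEFAULT_DILUTION_PURITIES,
    replicates: int = 3,
    n_snps: int = 12_000,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> list[dict]:
    """Signal-level analogue of a DNA purity-dilution experiment.

    Returns one record per (purity, replicate) — by default 7 purities
    (50/40/30/20/10/5/0%) x 3 replicates = 21 datasets — each tagged with its
    true purity and replicate index and carrying an independent SNP table.
    """
    if any(not 0.0 <= p <= 1.0 for p in purities):
        raise ValueError("purities must be in [0, 1]")
    base = np.random.default_rng(seed)
    out = []
    for purity in purities:
        for rep in range(replicates):
            child_seed = int(base.integers(2**31 - 1))
            out.append(
                {
                    "purity": float(purity),
                    "replicate": rep,
                    "seed": child_seed,
                    "snps": emit_snps(
                        profile, purity, n_snps=n_snps, noise_sd=noise_sd, seed=child_seed
                    ),
                }
            )
    return out


# ---------------------------------------------------------------------------
# clinical cohort simulation
# ---------------------------------------------------------------------------

_DEFAULT_MUTATION_RATES = {
    "BRCA2": 0.10,
    "BRCA1": 0.04,
    "TP53": 0.20,
    "MYC": 0.19,
    "ATM": 0.07,
    "CDK12": 0.06,
    "PTEN": 0.12,
    "RB1": 0.06,
    "SPOP": 0.08,
    "FOXA1": 0.10,
}

# additive shifts on the negative-binomial mean for mutated patients,
# emulating the reported score elevation in BRCA/MYC/TP53-mutant tumors
_DEFAULT_MUTATION_SHIFTS = {"BRCA2": 10.0, "BRCA1": 10.0, "MYC": 8.0, "TP53": 7.0}

ENDPOINTS = ("CFS", "MFS", "OS")
# baseline (low-score group) median survival in months per endpoint
_BASELINE_MEDIANS = {"CFS": 33.0, "MFS": 68.0, "OS": 90.0}


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a clinical cohort.

    Defaults emulate an aggressive prostate-cancer cohort of 123 patients:
    62.6% with intraductal carcinoma (IDC-P), ~75% of those pattern 2, 63.4%
    de novo metastatic, median HRD score 23 in IDC-P+ vs 14 in IDC-P-, and a
    hazard ratio ``hr_per_cutoff`` for patients at or above the score cutoff.
    """

    n_patients: int = 123
    prop_idcp: float = 77 / 123
    prop_pattern2_given_idcp: float = 58 / 77
    prop_m1: float = 78 / 123
    median_hrd_by_group: dict = field(
        default_factory=lambda: {"idcp_positive": 23, "idcp_negative": 14}
    )
    hr_per_cutoff: float = 2.5
    hrd_cutoff: int = 21
    censor_rate: float = 0.3
    nb_dispersion: float = 1.6
    prop_isup_high: float = 103 / 119
    prop_isup_missing: float = 4 / 123
    mutation_rates: dict = field(default_factory=lambda: dict(_DEFAULT_MUTATION_RATES))
    mutation_hrd_shift: dict = field(
        default_factory=lambda: dict(_DEFAULT_MUTATION_SHIFTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "prop_idcp",
            "prop_pattern2_given_idcp",
            "prop_m1",
            "censor_rate",
            "prop_isup_high",
            "prop_isup_missing",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hr_per_cutoff <= 0:
            raise ValueError("hr_per_cutoff must be > 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if any(m < 0 for m in self.median_hrd_by_group.values()):
            raise ValueError("group medians must be >= 0")


def _nb_mean_for_median(
    target_median: float,
    r: float,
    shift_mixture: Sequence[tuple[float, float]] = ((1.0, 0.0),),
) -> float:
    """Base mean of a negative-binomial family whose median equals the target.

    ``shift_mixture`` lists (probability, additive mean shift) components —
    e.g. the mutation-status mixture — so the *marginal* median of the drawn
    scores is calibrated, not just the unshifted component's.
    """
    if target_median <= 0:
        return 0.25  # nearly all mass at zero

    def mixture_cdf_at_target(mu: float) -> float:
        return sum(
            p * stats.nbinom.cdf(target_median, r, r / (r + mu + s))
            for p, s in shift_mixture
        )

    lo, hi = 0.01, max(10.0 * target_median, 10.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        # median <= target iff CDF(target) >= 0.5; larger mu -> smaller CDF
        if mixture_cdf_at_target(mid) >= 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _shift_mixture(
    rates: Mapping[str, float], shifts: Mapping[str, float]
) -> list[tuple[float, float]]:
    """Probability-weighted additive shifts over mutation-status combinations."""
    mix = [(1.0, 0.0)]
    for g, shift in shifts.items():
        if g not in rates:
            continue
        rate = rates[g]
        mix = [
            (p * w, s + extra)
            for p, s in mix
            for w, extra in ((1.0 - rate, 0.0), (rate, shift))
        ]
    return mix


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Draw a synthetic cohort with HRD-dependent survival.

    HRD scores come from a negative-binomial family (overdispersed counts;
    zeros possible) located so each group's median matches the spec, plus
    additive mean shifts for mutated genes.  Event times are exponential with
    log hazard ``log(hr_per_cutoff) * 1[score >= cutoff]``; censoring replaces
    an event with a uniform earlier time at rate ``censor_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    r = spec.nb_dispersion

    idcp = rng.random(n) < spec.prop_idcp
    pattern = np.where(
        idcp, np.where(rng.random(n) < spec.prop_pattern2_given_idcp, 2, 1), 0
    )
    m1 = rng.random(n) < spec.prop_m1
    isup_high = rng.random(n) < spec.prop_isup_high
    isup = np.where(isup_high, rng.integers(4, 6, n), rng.integers(1, 4, n)).astype(float)
    isup[rng.random(n) < spec.prop_isup_missing] = np.nan
    age = np.clip(rng.normal(68, 7, n).round(), 45, 92)
    psa = np.round(np.exp(rng.normal(math.log(65), 1.0, n)), 1)

    mix = _shift_mixture(spec.mutation_rates, spec.mutation_hrd_shift)
    mu_pos = _nb_mean_for_median(spec.median_hrd_by_group["idcp_positive"], r, mix)
    mu_neg = _nb_mean_for_median(spec.median_hrd_by_group["idcp_negative"], r, mix)
    mu = np.where(idcp, mu_pos, mu_neg).astype(float)

    genes = list(spec.mutation_rates)
    mut = {g: rng.random(n) < spec.mutation_rates[g] for g in genes}
    for g, shift in spec.mutation_hrd_shift.items():
        if g in mut:
            mu = mu + shift * mut[g]

    hrd = rng.negative_binomial(r, r / (r + mu))
    high = hrd >= spec.hrd_cutoff
    beta = math.log(spec.hr_per_cutoff)

    data = {
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "hrd_score": hrd,
        "idcp": np.select(
            [pattern == 1, pattern == 2],
            ["pattern1", "pattern2"],
            default="negative",
        ),
        "m_stage": np.where(m1, "M1", "M0"),
        "isup": isup,
        "age": age,
        "psa": psa,
    }
    for g in genes:
        data[g] = np.where(mut[g], "mutant", "wildtype")

    for ep in ENDPOINTS:
        lam = math.log(2.0) / _BASELINE_MEDIANS[ep] * np.exp(beta * high)
        t = rng.exponential(1.0 / lam)
        censored = rng.random(n) < spec.censor_rate
        t = np.where(censored, t * rng.random(n), t)
        data[f"{ep.lower()}_months"] = np.round(t, 1)
        data[f"{ep.lower()}_event"] = (~censored).astype(int)

    return pd.DataFrame(data)
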