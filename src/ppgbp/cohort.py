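"""Synthetic multi-site PPG--BP cohort generator.

The generator emulates the *statistical* structure that the
benchmarking pipeline assumes of real segment collections: per-site
SBP/DBP label distributions (normal, optionally with inflated tails for
device-validation style populations), multiple segments per subject
with subject-level setpoints and morphology effects, site-specific
segment lengths, sensor bandwidth and noise.

Blood pressure is deliberately encoded in *normalization-invariant
shape features* of the pulse, not in absolute amplitude:

* SBP -> timing of the reflected wave: the second pulse lags the
  systolic peak by ``delta = T * (d0 - d1 * (SBP - 120))`` (strictly
  decreasing in SBP), and additionally steepens the systolic upstroke
  (an asymmetric first pulse).
* DBP -> amplitude ratio of reflected to systolic pulse:
  ``r = clip(r0 + r1 * (DBP - 60), r_min, r_max)`` (strictly increasing
  in DBP).

Each beat is the sum of two Gaussian pulses with these parameters, plus
per-beat heart-rate jitter, additive white noise, 0.2 Hz baseline
wander, and a site low-pass filter.  Because training z-scores each
segment, amplitude-invariant encoding keeps the regression task
well-posed; :func:`decode_bp` provides the brute-force model inversion
that certifies identifiability.

This is NOT a physiologically validated pulse-wave model and makes no
claim of reproducing measured PPG morphology; it is a controllable
stand-in whose monotone shape--BP maps are what the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal

from .store import BP_MAX, BP_MIN, SegmentStore

__all__ = [
    "MorphologyMap", "SitePreset", "SubjectProfile", "CohortConfig",
    "CohortConfigurationError", "sample_subject_profiles",
    "synthesize_ppg_segment", "generate_cohort", "decode_bp", "decode_store",
    "detect_beat_minima", "measure_delay_ratio", "TABLE1_PRESETS",
    "make_preset", "noiseless_config", "zscore",
]


class CohortConfigurationError(ValueError):
    pass


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class MorphologyMap:
    """Constants mapping (SBP, DBP, subject effects) to beat shape.

    Fractions are relative to the beat period T.  The constants are
    arbitrary but fixed; downstream code relies only on the monotone,
    invertible structure of the maps, never on the specific values.
    """

    mu1_frac: float = 0.15      # systolic peak time / T
    sigma1_frac: float = 0.08   # systolic pulse width / T
    sigma2_frac: float = 0.12   # reflected pulse width / T
    d0: float = 0.30            # reflected-wave delay fraction at SBP=120
    d1: float = 0.0010          # delay decrease per mmHg SBP
    r0: float = 0.30            # amplitude ratio at DBP=60
    r1: float = 0.004           # ratio increase per mmHg DBP
    r_min: float = 0.10
    r_max: float = 0.80
    upstroke_coeff: float = 0.003  # systolic left-width shrink per mmHg SBP
    subject_delta_sd: float = 0.01  # subject random effect on delta (units of T)
    subject_ratio_sd: float = 0.03  # subject random effect on r

    def delta_frac(self, sbp, delta_offset=0.0):
        raw = self.d0 - self.d1 * (np.asarray(sbp, dtype=float) - 120.0) + delta_offset
        return np.clip(raw, 0.02, 0.98 - self.mu1_frac)

    def ratio(self, dbp, ratio_offset=0.0):
        raw = self.r0 + self.r1 * (np.asarray(dbp, dtype=float) - 60.0) + ratio_offset
        return np.clip(raw, self.r_min, self.r_max)

    def upstroke_factor(self, sbp):
        return np.clip(1.0 - self.upstroke_coeff * (np.asarray(sbp, dtype=float) - 120.0),
                       0.5, 1.5)

    def invert_delta(self, delta_frac):
        """SBP (mmHg) from a measured delay fraction (inverse of delta_frac)."""
        return 120.0 + (self.d0 - delta_frac) / self.d1

    def invert_ratio(self, r):
        """DBP (mmHg) from a measured amplitude ratio (inverse of ratio)."""
        return 60.0 + (r - self.r0) / self.r1

    def validate(self) -> None:
        bp = np.arange(BP_MIN, BP_MAX + 1.0)
        d = self.d0 - self.d1 * (bp - 120.0)
        if not ((self.mu1_frac > 0) and (self.mu1_frac + d < 1).all() and (d > 0).all()):
            raise CohortConfigurationError("pulse timing leaves the beat window")
        if not (0 < self.r_min < self.r_max < 1):
            raise CohortConfigurationError("ratio clip range must lie in (0, 1)")
        if self.d1 <= 0 or self.r1 <= 0:
            raise CohortConfigurationError("delta must decrease and r increase with BP")


@dataclass(frozen=True)
class SitePreset:
    """One site of a synthetic study: label distribution + sensor model."""

    name: str
    sbp_mean: float
    sbp_sd: float
    dbp_mean: float
    dbp_sd: float
    n_subjects: int
    segments_per_subject: int = 10
    segment_seconds: float = 10.0
    fs: float = 125.0
    noise_sd: float = 0.03          # additive white noise, relative amplitude
    wander_amp: float = 0.10        # 0.2 Hz baseline wander amplitude
    bandpass_cutoff: float = 16.0   # site low-pass (sensor bandwidth), Hz
    hr_mean: float = 70.0
    hr_sd: float = 8.0
    hr_jitter_sd: float = 0.02      # per-beat relative period jitter
    within_sbp_sd: float = 6.0      # within-subject segment-to-segment BP, mmHg
    within_dbp_sd: float = 4.0
    bp_correlation: float = 0.7     # SBP-DBP setpoint correlation (physiologic)

    @property
    def segment_len(self) -> int:
        return int(round(self.segment_seconds * self.fs))

    def validate(self) -> None:
        if self.sbp_mean <= self.dbp_mean:
            raise CohortConfigurationError(f"{self.name}: sbp_mean <= dbp_mean")
        if min(self.sbp_sd, self.dbp_sd, self.hr_sd) < 0:
            raise CohortConfigurationError(f"{self.name}: negative SD")
        if self.segment_len < 100:
            raise CohortConfigurationError(
                f"{self.name}: segment length {self.segment_len} < 100 samples")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    sbp_setpoint: float
    dbp_setpoint: float
    hr: float
    delta_offset: float = 0.0
    ratio_offset: float = 0.0
    within_sbp_sd: float = 6.0
    within_dbp_sd: float = 4.0


@dataclass(frozen=True)
class CohortConfig:
    sites: tuple[SitePreset, ...]
    morphology: MorphologyMap = MorphologyMap()
    seed: int = 0
    tail_boost: dict = field(default_factory=dict)  # site name -> mixture weight

    def validate(self) -> None:
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise CohortConfigurationError("site names must be unique")
        self.morphology.validate()
        for s in self.sites:
            s.validate()
        for name in self.tail_boost:
            if name not in names:
                raise CohortConfigurationError(f"tail_boost for unknown site {name!r}")


# ----------------------------------------------------------------------
# Published label statistics of the six emulated datasets (SBP/DBP
# mean +- SD in mmHg), with their segment lengths and subject counts.
_TABLE1 = {
    # name: (sbp_mean, sbp_sd, dbp_mean, dbp_sd, n_subjects, seconds)
    "mimic":   (123.32, 23.00, 61.58, 13.48, 1474, 10.0),
    "vitaldb": (115.62, 18.92, 63.03, 12.05, 1553, 10.0),
    "sensors": (134.36, 21.78, 65.37, 10.51, 1195, 5.0),
    "uci":     (131.57, 11.16, 66.79, 10.48, 10793, 5.0),
    "bcg":     (120.99, 15.29, 67.23, 9.30, 40, 5.0),
    "ppgbp":   (128.02, 20.50, 71.91, 11.20, 218, 2.1),
}


def make_preset(name: str, subject_scale: float = 1.0,
                segments_per_subject: int = 10, **overrides) -> SitePreset:
    """Site preset for one of the six emulated datasets.

    ``subject_scale`` shrinks the published subject count for desk-scale
    studies (minimum 4 subjects); other fields may be overridden.
    """
    if name not in _TABLE1:
        raise CohortConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_TABLE1)}")
    sbp_m, sbp_s, dbp_m, dbp_s, n_subj, seconds = _TABLE1[name]
    preset = SitePreset(name=name, sbp_mean=sbp_m, sbp_sd=sbp_s,
                        dbp_mean=dbp_m, dbp_sd=dbp_s,
                        n_subjects=max(4, int(round(n_subj * subject_scale))),
                        segments_per_subject=segments_per_subject,
                        segment_seconds=seconds)
    return replace(preset, **overrides) if overrides else preset


TABLE1_PRESETS = {name: make_preset(name) for name in _TABLE1}


def noiseless_config(preset: SitePreset, seed: int = 0) -> CohortConfig:
    """Cohort with every stochastic nuisance off: used by the
    identifiability oracle (shape -> BP must be exactly invertible)."""
    clean = replace(preset, noise_sd=0.0, wander_amp=0.0, hr_jitter_sd=0.0,
                    bandpass_cutoff=55.0)
    morph = replace(MorphologyMap(), subject_delta_sd=0.0, subject_ratio_sd=0.0)
    return CohortConfig(sites=(clean,), morphology=morph, seed=seed)


# ----------------------------------------------------------------------
def sample_subject_profiles(preset: SitePreset, morphology: MorphologyMap,
                            rng: np.random.Generator,
                            tail_boost: float = 0.0) -> list[SubjectProfile]:
    """Draw subject BP setpoints from the site's label distribution.

    SBP and DBP are drawn jointly with the preset's correlation (the
    marginals stay normal with the published mean/SD) and
    rejection-resampled until SBP - DBP >= 15 mmHg and both lie within
    the physiologic range; the correlated draw keeps the rejection rate
    (and hence the truncation bias on the means) negligible.
    ``tail_boost`` mixes in a wide-tailed component (SD inflated 2.5x)
    with the given weight to emulate validation populations emphasizing
    BP extremes.
    """
    preset.validate()
    rho = float(np.clip(preset.bp_correlation, -0.99, 0.99))
    profiles = []
    for j in range(preset.n_subjects):
        for attempt in range(1000):
            widen = 2.5 if (tail_boost > 0 and rng.random() < tail_boost) else 1.0
            z1, z2 = rng.standard_normal(2)
            sbp = preset.sbp_mean + widen * preset.sbp_sd * z1
            dbp = preset.dbp_mean + widen * preset.dbp_sd * (
                rho * z1 + np.sqrt(1 - rho * rho) * z2)
            if (sbp - dbp >= 15.0 and BP_MIN <= dbp and sbp <= BP_MAX
                    and dbp <= BP_MAX and sbp >= BP_MIN):
                break
        else:
            raise CohortConfigurationError(
                f"could not sample a valid setpoint for subject {j} of "
                f"site {preset.name!r} after 1000 tries")
        profiles.append(SubjectProfile(
            subject_id=f"{preset.name}_s{j:04d}",
            sbp_setpoint=float(sbp), dbp_setpoint=float(dbp),
            hr=float(np.clip(rng.normal(preset.hr_mean, preset.hr_sd), 40.0, 140.0)),
            delta_offset=float(rng.normal(0.0, morphology.subject_delta_sd)),
            ratio_offset=float(rng.normal(0.0, morphology.subject_ratio_sd)),
            within_sbp_sd=preset.within_sbp_sd,
            within_dbp_sd=preset.within_dbp_sd))
    return profiles


def _asym_gauss(t: np.ndarray, mu: float, sd_left: float, sd_right: float) -> np.ndarray:
    sd = np.where(t < mu, sd_left, sd_right)
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def synthesize_ppg_segment(sbp: float, dbp: float, hr: float,
                           profile_offsets: tuple[float, float],
                           preset: SitePreset, morphology: MorphologyMap,
                           rng: np.random.Generator) -> np.ndarray:
    """One segment: concatenated two-Gaussian beats + noise + wander + filter."""
    if not sbp > dbp:
        raise ValueError(f"sbp ({sbp}) must exceed dbp ({dbp})")
    if not 30.0 <= hr <= 180.0:
        raise ValueError(f"hr {hr} outside [30, 180] bpm")
    delta_off, ratio_off = profile_offsets
    n = preset.segment_len
    fs = preset.fs
    t = np.arange(n) / fs
    duration = n / fs
    T0 = 60.0 / hr

    d_frac = float(morphology.delta_frac(sbp, delta_off))
    r = float(morphology.ratio(dbp, ratio_off))
    up = float(morphology.upstroke_factor(sbp))

    x = np.zeros(n)
    onset = 0.0
    while onset < duration + T0:
        T = T0 * (1.0 + (rng.normal(0.0, preset.hr_jitter_sd)
                         if preset.hr_jitter_sd > 0 else 0.0))
        mu1 = onset + morphology.mu1_frac * T
        s1 = morphology.sigma1_frac * T
        s2 = morphology.sigma2_frac * T
        x += _asym_gauss(t, mu1, up * s1, s1)
        x += r * np.exp(-0.5 * ((t - (mu1 + d_frac * T)) / s2) ** 2)
        onset += T
    # trailing tail of the beat before t=0 (periodic continuation)
    Tpre = T0
    mu1 = -Tpre + morphology.mu1_frac * Tpre
    x += _asym_gauss(t, mu1, up * morphology.sigma1_frac * Tpre,
                     morphology.sigma1_frac * Tpre)
    x += r * np.exp(-0.5 * ((t - (mu1 + d_frac * Tpre))
                            / (morphology.sigma2_frac * Tpre)) ** 2)

    if preset.wander_amp > 0:
        x += preset.wander_amp * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    if preset.noise_sd > 0:
        x += rng.normal(0.0, preset.noise_sd, size=n)
    if preset.bandpass_cutoff < 0.49 * fs:
        sos = signal.butter(4, preset.bandpass_cutoff, btype="low", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)  # zero-phase: preserves pulse timing
    return x


def generate_cohort(config: CohortConfig) -> SegmentStore:
    """Generate the full multi-site store; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    signals, sbps, dbps, subjects, sites = [], [], [], [], []
    fs = config.sites[0].fs
    for preset in config.sites:
        if preset.fs != fs:
            raise CohortConfigurationError("all sites must share one sampling rate")
        profiles = sample_subject_profiles(
            preset, config.morphology, rng,
            tail_boost=float(config.tail_boost.get(preset.name, 0.0)))
        for prof in profiles:
            for _ in range(preset.segments_per_subject):
                for _attempt in range(1000):
                    sbp = prof.sbp_setpoint + rng.normal(0.0, prof.within_sbp_sd) \
                        if prof.within_sbp_sd > 0 else prof.sbp_setpoint
                    dbp = prof.dbp_setpoint + rng.normal(0.0, prof.within_dbp_sd) \
                        if prof.within_dbp_sd > 0 else prof.dbp_setpoint
                    if sbp - dbp >= 10.0 and BP_MIN <= dbp and sbp <= BP_MAX:
                        break
                else:  # pragma: no cover - requires pathological config
                    raise CohortConfigurationError(
                        f"could not draw a valid segment BP for {prof.subject_id}")
                x = synthesize_ppg_segment(
                    sbp, dbp, prof.hr, (prof.delta_offset, prof.ratio_offset),
                    preset, config.morphology, rng)
                signals.append(x)
                sbps.append(sbp)
                dbps.append(dbp)
                subjects.append(prof.subject_id)
                sites.append(preset.name)
    return SegmentStore(signals=np.array(signals, dtype=object)
                        if signals else np.empty(0, dtype=object),
                        sbp=np.array(sbps), dbp=np.array(dbps),
                        subject_id=np.array(subjects, dtype=str),
                        site_id=np.array(sites, dtype=str),
                        fs=fs, attrs={"seed": int(config.seed)})


# ----------------------------------------------------------------------
def cohort_config_to_dict(config: CohortConfig) -> dict:
    from dataclasses import asdict
    return {"seed": config.seed,
            "morphology": asdict(config.morphology),
            "tail_boost": dict(config.tail_boost),
            "sites": [asdict(s) for s in config.sites]}


def cohort_config_from_dict(d: dict) -> CohortConfig:
    cfg = CohortConfig(
        sites=tuple(SitePreset(**s) for s in d.get("sites", [])),
        morphology=MorphologyMap(**d.get("morphology", {})),
        seed=int(d.get("seed", 0)),
        tail_boost=dict(d.get("tail_boost", {})))
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------
# brute-force inversion oracle
# ----------------------------------------------------------------------

def zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 1e-12 else 1.0)


def detect_beat_minima(x: np.ndarray, fs: float) -> np.ndarray:
    """Brute-force beat boundary detection: local minima separated by at
    least the plausible minimum beat period (HR <= 180 bpm)."""
    min_dist = int(fs * 60.0 / 180.0)
    idx, _ = signal.find_peaks(-x, distance=min_dist,
                               prominence=0.1 * (x.max() - x.min()))
    return idx


def _estimate_period(x: np.ndarray, fs: float) -> float:
    """Beat period in seconds from the autocorrelation peak."""
    xc = x - x.mean()
    ac = np.correlate(xc, xc, mode="full")[len(xc) - 1:]
    lo = int(fs * 60.0 / 180.0)
    hi = min(int(fs * 60.0 / 30.0), len(ac) - 2)
    if hi <= lo:
        raise ValueError("segment too short to estimate a beat period")
    lag = lo + int(np.argmax(ac[lo:hi]))
    # parabolic sub-sample refinement
    a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
    denom = a - 2 * b + c
    shift = 0.5 * (a - c) / denom if abs(denom) > 1e-12 else 0.0
    return (lag + float(np.clip(shift, -1, 1))) / fs


def measure_delay_ratio(x: np.ndarray, fs: float,
                        morphology: MorphologyMap) -> tuple[float, float]:
    """Argmax-free template measurement: least-squares fit of the
    periodic two-Gaussian beat train to the segment.

    Returns (delta_frac, r).  Works on raw or z-scored segments because
    an affine amplitude transform is part of the fitted model.
    """
    T0 = _estimate_period(x, fs)
    n = len(x)
    t = np.arange(n) / fs

    def model(params):
        T, phi, amp, off, d_frac, r, up = params
        y = np.full(n, off)
        onset = phi - T * np.ceil((phi) / T + 1)
        while onset < n / fs + T:
            mu1 = onset + morphology.mu1_frac * T
            s1 = morphology.sigma1_frac * T
            y = y + amp * _asym_gauss(t, mu1, up * s1, s1)
            y = y + amp * r * np.exp(
                -0.5 * ((t - (mu1 + d_frac * T)) / (morphology.sigma2_frac * T)) ** 2)
            onset += T
        return y

    # initial phase: align first systolic peak
    peak0 = int(np.argmax(x[: int(1.5 * T0 * fs)]))
    phi0 = peak0 / fs - morphology.mu1_frac * T0
    amp0 = float(x.max() - x.min())
    x0 = np.array([T0, phi0, amp0, float(np.median(x)),
                   morphology.d0, morphology.r0, 1.0])
    lo = [T0 * 0.8, phi0 - T0 / 2, 1e-6 * amp0, -np.inf, 0.02, 0.01, 0.4]
    hi = [T0 * 1.2, phi0 + T0 / 2, 10 * amp0, np.inf, 0.9, 0.95, 1.6]
    res = optimize.least_squares(lambda p: model(p) - x, x0, bounds=(lo, hi),
                                 method="trf", xtol=1e-12, ftol=1e-12)
    T, _, _, _, d_frac, r, _ = res.x
    return float(d_frac), float(r)


def decode_bp(x: np.ndarray, fs: float,
              morphology: MorphologyMap) -> tuple[float, float]:
    """Brute-force inverse of the generator: measure the shape features
    and invert the monotone maps.  Independent of any trained model."""
    d_frac, r = measure_delay_ratio(x, fs, morphology)
    return float(morphology.invert_delta(d_frac)), float(morphology.invert_ratio(r))


def decode_store(store: SegmentStore, morphology: MorphologyMap,
                 zscore_first: bool = False) -> tuple[np.ndarray, np.ndarray]:
    sbp, dbp = [], []
    for x in store.signals:
        xin = zscore(x) if zscore_first else x
        s, d = decode_bp(xin, store.fs, morphology)
        sbp.append(s)
        dbp.append(d)
    return np.array(sbp), np.array(dbp)
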