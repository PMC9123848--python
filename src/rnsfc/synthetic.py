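"""Synthetic MEG-like cohort generator with planted connectivity.

The generator emulates the statistical structure the downstream analysis
assumes, not the biophysics of MEG acquisition:

* each ROI carries independent 1/f-shaped Gaussian background noise, plus
  a small zero-lag "leakage" component shared by every ROI (the
  volume-conduction confound that imaginary coherence is built to ignore);
* a coupled module pair shares a narrowband source mixed into all ROIs of
  both modules, with one side delayed by a phase lag (default a quarter
  cycle of the band's center frequency, which maximizes the imaginary
  part of the coherency);
* the mixing coefficient is calibrated numerically against the analytic
  coherency of the two-signal lagged-common-source model, so the measured
  band imaginary coherence of a coupled pair converges to the requested
  ``strength`` as the recording grows.

Cohorts mirror the clinical study design: healthy controls at baseline
coupling, responders with elevated alpha coupling, non-responders with
reduced alpha and beta coupling, and a monotone (affine) link from each
patient's planted alpha coupling to percent seizure reduction with
additive Gaussian noise.  Responder labels are then assigned by the
>= 50% reduction rule.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize, signal, stats

from ._rng import child_seed, substream
from .bands import CANONICAL_BANDS, get_band
from .containers import EPOCH_LEN_S, RoiTimeSeries
from .outcomes import SubjectOutcome, responder_label
from .parcellation import Parcellation
from .spectral import _bandpass_sos

#: corner below which the 1/f background spectrum flattens, Hz
PINK_FLOOR_HZ = 1.0


# ---------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class CouplingSpec:
    """A planted band-limited coupling between module pairs.

    ``strength`` is the target band-averaged imaginary coherence of each
    listed pair; ``lag`` the phase offset (radians) applied to the second
    module's copy of the shared source at the band's center frequency.
    """

    band: str
    pairs: tuple[tuple[int, int], ...]
    strength: float
    lag: float = math.pi / 2

    def __post_init__(self) -> None:
        if self.band not in CANONICAL_BANDS:
            raise ValueError(
                f"band must be one of {sorted(CANONICAL_BANDS)}, got {self.band!r}"
            )
        if not 0 <= self.strength < 1:
            raise ValueError(f"strength must be in [0, 1), got {self.strength}")
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"coupled pair must have i < j, got ({i}, {j})")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort sizes, acquisition parameters and planted group effects.

    Connectivity shifts are expressed on the imaginary-coherence scale and
    are applied to the baseline coupling strength of the affected band;
    ``subject_strength_sd`` is the between-subject spread of planted
    strengths (shared by controls and patients, so the control reference
    carries realistic inter-subject variability).
    """

    n_controls: int = 15
    n_responders: int = 22
    n_nonresponders: int = 9
    sampling_rate: float = 200.0
    duration: float = 120.0
    baseline_strength: float = 0.30
    responder_alpha_shift: float = 0.15
    nonresponder_alpha_shift: float = -0.15
    nonresponder_beta_shift: float = -0.15
    subject_strength_sd: float = 0.10
    outcome_noise_sd: float = 10.0
    outcome_slope: float = 150.0
    leak: float = 0.4
    intra_module_lag_frac: float = 0.05
    clean_epoch_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_responders, self.n_nonresponders) < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.duration < 90.0:
            raise ValueError(
                f"duration must be >= 90 s (six 15 s epochs), got {self.duration}"
            )
        top = max(b.f_hi for b in CANONICAL_BANDS.values())
        if self.sampling_rate <= 2 * top:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz violates Nyquist for the "
                f"{top} Hz top band edge (need > {2 * top} Hz)"
            )


# ---------------------------------------------------------------------------
# mixing-strength calibration

@lru_cache(maxsize=None)
def _psd_grids(band_name: str, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fine grid, background PSD, source PSD) around a band.

    Both PSDs are one-sided densities of unit-variance processes: the
    1/f-shaped background and the order-4 Butterworth (two-pass) filtered
    white source.  The grid extends a few Hz beyond the band edges so the
    spectral-window smearing of the estimator can be modeled.
    """
    band = get_band(band_name)
    full = np.linspace(0.05, fs / 2, 8192)
    pink = 1.0 / np.maximum(full, PINK_FLOOR_HZ)
    pink /= np.trapezoid(pink, full)
    _, h = signal.sosfreqz(_bandpass_sos(band, fs), worN=full, fs=fs)
    src = np.abs(h) ** 4  # two passes of the order-4 filter
    src /= np.trapezoid(src, full)
    lo = max(0.05, band.f_lo - 5.0)
    hi = min(fs / 2, band.f_hi + 5.0)
    grid = np.arange(lo, hi, 0.05)
    return (
        grid,
        np.interp(grid, full, pink),
        np.interp(grid, full, src),
    )


@lru_cache(maxsize=None)
def _window_kernel(fs: float, window_len: float) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral kernel of the Hann analysis window (offset grid, K)."""
    nperseg = int(round(window_len * fs))
    win = signal.get_window("hann", nperseg)
    nfft = 64 * nperseg
    k = np.abs(np.fft.rfft(win, nfft)) ** 2
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    keep = f <= 4.0 / window_len  # main lobe + first side lobes
    offs = np.concatenate([-f[keep][:0:-1], f[keep]])
    kern = np.concatenate([k[keep][:0:-1], k[keep]])
    return offs, kern / np.trapezoid(kern, offs)


def max_strength(band: str, lag: float = math.pi / 2, fs: float = 200.0,
                 window_len: float = 1.0) -> float:
    """Largest achievable band ImCoh for a lagged common source.

    The underlying ceiling is the band average of |sin(2 pi f tau)|,
    reached as the mixing dominates the background; what the estimator can
    see is slightly lower because its spectral window smears the band
    edges, so the ceiling is evaluated through the same forward model used
    for calibration.
    """
    return _predicted_imcoh(1e8, band, lag, fs, 1.0, window_len)


@lru_cache(maxsize=None)
def _forward_model(
    band: str, lag: float, fs: float, window_len: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin integrals of the estimator's forward model.

    The Welch estimate at an analysis bin is the true spectrum smeared by
    the Hann window's power kernel K, so for each in-band bin f_k this
    precomputes

        a_k = |int K(v - f_k) Ps(v) sin(2 pi v tau) dv|   (imag cross part)
        b_k =  int K(v - f_k) Ps(v) dv                    (source power)
        c_k =  int K(v - f_k) Pn(v) dv                    (background power)

    for the unit-variance source and background spectral shapes.
    """
    b = get_band(band)
    grid, pn, ps = _psd_grids(b.name if b.name in CANONICAL_BANDS else band, fs)
    tau = lag / (2 * math.pi * b.center)
    offs, kern = _window_kernel(fs, window_len)
    df = 1.0 / window_len
    bins = np.arange(math.ceil(b.f_lo / df) * df, b.f_hi + 1e-9, df)
    dv = grid[1] - grid[0]
    w = np.stack([np.interp(grid - f, offs, kern, left=0.0, right=0.0) for f in bins])
    a = np.abs(w @ (ps * np.sin(2 * math.pi * grid * tau))) * dv
    return a, (w @ ps) * dv, (w @ pn) * dv


def _predicted_imcoh(
    g2: float, band: str, lag: float, fs: float,
    background_scale: float, window_len: float,
    extra_i: float = 0.0, extra_j: float = 0.0,
) -> float:
    """Band ImCoh the default estimator would see for a coupled pair.

    ``extra_i``/``extra_j`` are additional in-band source powers (g^2 of
    other couplings) present in each channel but not shared between them
    -- e.g. when a module participates in more than one coupled pair.
    """
    a, b, c = _forward_model(band, lag, fs, window_len)
    den_i = (g2 + extra_i) * b + background_scale * c
    den_j = (g2 + extra_j) * b + background_scale * c
    return float(np.mean(g2 * a / np.sqrt(den_i * den_j)))


@lru_cache(maxsize=65536)
def mixing_coefficient(
    strength: float,
    band: str,
    lag: float = math.pi / 2,
    fs: float = 200.0,
    background_scale: float = 1.0,
    window_len: float = 1.0,
    extra_i: float = 0.0,
    extra_j: float = 0.0,
) -> float:
    """Mixing amplitude g achieving the target band ImCoh.

    Solved numerically against the analytic coherency of the lagged
    common-source model as seen by the default Welch estimator
    (:func:`_predicted_imcoh`); results are cached per (strength, band,
    lag, rate) so cohort simulation does not re-solve.
    ``background_scale`` inflates the background PSD (e.g. 1 + leak^2
    when a shared leakage source is mixed into every channel).

    For (near-)zero lag the imaginary part is ~0 no matter the mixing;
    the coherency *magnitude* is calibrated instead so the
    volume-conduction null remains exercisable at a defined mixing level.
    """
    if strength == 0:
        return 0.0
    b = get_band(band)
    tau = lag / (2 * math.pi * b.center)
    grid_chk = np.linspace(b.f_lo, b.f_hi, 64)
    smax = float(np.mean(np.abs(np.sin(2 * math.pi * grid_chk * tau))))
    if smax < 1e-3:
        grid, pn, ps = _psd_grids(b.name if b.name in CANONICAL_BANDS else band, fs)
        pn = pn * background_scale
        mask = (grid >= b.f_lo) & (grid <= b.f_hi)

        def gap(g2: float) -> float:
            gamma = g2 * ps[mask] / (g2 * ps[mask] + pn[mask])
            return float(gamma.mean()) - strength

        return math.sqrt(optimize.brentq(gap, 1e-12, 1e8, rtol=1e-10))
    ceiling = _predicted_imcoh(1e8, band, lag, fs, background_scale, window_len,
                               extra_i, extra_j)
    if strength >= 0.995 * ceiling:
        raise ValueError(
            f"target strength {strength:.3f} is infeasible for band {band!r} at "
            f"lag {lag:.3f} (estimator ceiling {ceiling:.3f})"
        )

    def gap(g2: float) -> float:
        return _predicted_imcoh(g2, band, lag, fs, background_scale, window_len,
                                extra_i, extra_j) - strength

    g2 = optimize.brentq(gap, 1e-12, 1e8, rtol=1e-10)
    return math.sqrt(g2)


# ---------------------------------------------------------------------------
# signal generation

def _colored_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise (flat below the corner)."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(f, PINK_FLOOR_HZ))
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _band_source(rng: np.random.Generator, n: int, fs: float, band: str) -> np.ndarray:
    """Unit-variance narrowband Gaussian source."""
    s = signal.sosfiltfilt(_bandpass_sos(get_band(band), fs), rng.standard_normal(n))
    return s / s.std()


def _delayed(x: np.ndarray, tau: float, fs: float) -> np.ndarray:
    """Circularly delay a signal by ``tau`` seconds (frequency domain)."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    return np.fft.irfft(spec * np.exp(-2j * math.pi * f * tau), n=x.size)


def simulate_subject(
    design: CohortDesign,
    parcellation: Parcellation,
    couplings: Sequence[CouplingSpec],
    seed: int,
) -> RoiTimeSeries:
    """One subject's ROI time series with the requested planted couplings."""
    fs = design.sampling_rate
    for spec in couplings:
        band = get_band(spec.band)
        if band.f_hi >= fs / 2:
            raise ValueError(
                f"band {spec.band!r} upper edge {band.f_hi} Hz violates the "
                f"Nyquist limit {fs / 2:.1f} Hz at sampling rate {fs} Hz"
            )
    rng = np.random.default_rng(int(seed) % 2**31)
    n = int(round(design.duration * fs))
    data = _colored_noise(rng, parcellation.n_rois, n, fs)
    data += design.leak * _colored_noise(rng, 1, n, fs)
    rows = parcellation.module_rows(parcellation.roi_ids)
    bg_scale = 1.0 + design.leak**2
    # modules may participate in several coupled pairs of one band (chain
    # topologies); the extra unshared source power in such channels is fed
    # back into the per-pair calibration by fixed-point refinement
    pair_g: dict[tuple[int, tuple[int, int]], float] = {}
    active = [
        (k, spec) for k, spec in enumerate(couplings)
        if spec.strength > 0 and spec.pairs
    ]
    for k, spec in active:
        for pair in spec.pairs:
            pair_g[(k, pair)] = mixing_coefficient(
                spec.strength, spec.band, spec.lag, fs, bg_scale
            )
    for _ in range(3):
        power: dict[tuple[str, int], float] = {}
        for k, spec in active:
            for i, j in spec.pairs:
                g2 = pair_g[(k, (i, j))] ** 2
                power[(spec.band, i)] = power.get((spec.band, i), 0.0) + g2
                power[(spec.band, j)] = power.get((spec.band, j), 0.0) + g2
        for k, spec in active:
            for i, j in spec.pairs:
                g2 = pair_g[(k, (i, j))] ** 2
                pair_g[(k, (i, j))] = mixing_coefficient(
                    spec.strength, spec.band, spec.lag, fs, bg_scale,
                    extra_i=round(power[(spec.band, i)] - g2, 5),
                    extra_j=round(power[(spec.band, j)] - g2, 5),
                )
    for k, spec in active:
        tau = spec.lag / (2 * math.pi * get_band(spec.band).center)
        # small per-ROI conduction delay within each module: member k of a
        # module receives the source delayed by an extra k * frac * tau.
        # At the quarter-cycle default lag the cross-module calibration is
        # second-order insensitive to this, while within-module coherence
        # acquires a small imaginary part that grows with the coupling.
        eps = design.intra_module_lag_frac * tau
        for i, j in spec.pairs:
            if i not in rows or j not in rows:
                raise KeyError(f"coupled pair ({i}, {j}) references unknown modules")
            g = pair_g[(k, (i, j))]
            src = _band_source(rng, n, fs, spec.band)
            for m, row in enumerate(rows[i]):
                data[row] += g * _delayed(src, m * eps, fs)
            for m, row in enumerate(rows[j]):
                data[row] += g * _delayed(src, tau + m * eps, fs)
    n_epochs = int(design.duration // EPOCH_LEN_S)
    flags = rng.random(n_epochs) < design.clean_epoch_prob
    short = 6 - int(flags.sum())
    if short > 0:  # guarantee the six clean epochs the analysis needs
        flags[np.flatnonzero(~flags)[:short]] = True
    return RoiTimeSeries(
        subject_id=f"sub-{seed}",
        sampling_rate=fs,
        roi_ids=parcellation.roi_ids,
        data=data,
        epoch_flags=flags,
    )


# ---------------------------------------------------------------------------
# cohort planning

@dataclass
class SubjectPlan:
    """Ground-truth record for one planned subject."""

    subject_id: str
    designed_group: str  # "control" | "R" | "NR"
    sim_seed: int
    couplings: tuple[CouplingSpec, ...]
    alpha_strength: float
    beta_strength: float
    noiseless_reduction: float | None = None
    outcome: SubjectOutcome | None = None


@dataclass
class CohortPlan:
    """Deterministic blueprint of a synthetic cohort (no time series)."""

    design: CohortDesign
    parcellation: Parcellation
    subjects: list[SubjectPlan]

    @property
    def controls(self) -> list[SubjectPlan]:
        return [s for s in self.subjects if s.designed_group == "control"]

    @property
    def patients(self) -> list[SubjectPlan]:
        return [s for s in self.subjects if s.designed_group != "control"]

    def truth(self) -> dict:
        return {
            s.subject_id: {
                "designed_group": s.designed_group,
                "alpha_strength": s.alpha_strength,
                "beta_strength": s.beta_strength,
                "noiseless_reduction": s.noiseless_reduction,
                "sim_seed": s.sim_seed,
            }
            for s in self.subjects
        }


def default_coupling_pairs(parcellation: Parcellation) -> tuple[tuple[int, int], ...]:
    """Within-hemisphere chains of consecutive modules.

    Chaining (m0,m1), (m1,m2), ... couples most of the network, matching
    the spatially extensive connectivity phenotype the cohorts emulate;
    interior modules carry two band sources, which the per-pair
    calibration accounts for.
    """
    pairs = []
    for h in ("L", "R"):
        mods = parcellation.modules_in(hemisphere=h)
        for k in range(len(mods) - 1):
            pairs.append((mods[k], mods[k + 1]))
    return tuple(pairs)


def _draw_strength(rng, base: float, shift: float, sd: float, ceiling: float) -> float:
    return float(np.clip(base + shift + rng.normal(0.0, sd), 0.02, ceiling))


def _link(design: CohortDesign, alpha: float) -> float:
    """Noiseless affine alpha-coupling -> percent-reduction link."""
    r = 50.0 + design.outcome_slope * (alpha - design.baseline_strength)
    return float(np.clip(r, -100.0, 100.0))


def plan_cohort(design: CohortDesign, parcellation: Parcellation) -> CohortPlan:
    """Plan a full cohort: planted strengths, outcomes and metadata.

    All randomness flows from ``design.seed`` through named substreams, so
    the plan (and the simulated time series derived from it) is
    reproducible bit-for-bit.
    """
    rng_s = substream(design.seed, "strengths")
    rng_o = substream(design.seed, "outcomes")
    rng_m = substream(design.seed, "metadata")
    pairs = default_coupling_pairs(parcellation)
    a_max = 0.95 * max_strength("alpha")
    b_max = 0.95 * max_strength("beta")
    lobe_names = parcellation.lobes

    groups = (
        ["control"] * design.n_controls
        + ["R"] * design.n_responders
        + ["NR"] * design.n_nonresponders
    )
    subjects: list[SubjectPlan] = []
    i_ctrl = i_pat = 0
    for g in groups:
        a_shift = {"control": 0.0, "R": design.responder_alpha_shift,
                   "NR": design.nonresponder_alpha_shift}[g]
        b_shift = {"control": 0.0, "R": 0.0,
                   "NR": design.nonresponder_beta_shift}[g]
        alpha = _draw_strength(rng_s, design.baseline_strength, a_shift,
                               design.subject_strength_sd, a_max)
        beta = _draw_strength(rng_s, design.baseline_strength, b_shift,
                              design.subject_strength_sd, b_max)
        couplings = (
            CouplingSpec("alpha", pairs, alpha),
            CouplingSpec("beta", pairs, beta),
        )
        if g == "control":
            sid = f"ctrl-{i_ctrl:02d}"
            i_ctrl += 1
            subjects.append(
                SubjectPlan(sid, g, child_seed(design.seed, "sim", sid),
                            couplings, alpha, beta)
            )
            continue
        sid = f"pat-{i_pat:02d}"
        i_pat += 1
        noiseless = _link(design, alpha)
        reduction = float(
            np.clip(noiseless + rng_o.normal(0.0, design.outcome_noise_sd),
                    -100.0, 100.0)
        )
        baseline = float(np.clip(np.exp(rng_o.normal(np.log(3.5), 0.9)), 0.25, 60.0))
        current = baseline * (1.0 - reduction / 100.0)
        eta = rng_o.uniform(0.0, 0.15)
        hemis = {"L": ("L",), "R": ("R",), "LR": ("L", "R")}[
            rng_m.choice(["L", "R", "LR"], p=[0.7, 0.2, 0.1])
        ]
        n_lobes = 1 if rng_m.random() < 0.7 else 2
        lobes = tuple(rng_m.choice(lobe_names, size=n_lobes, replace=False))
        outcome = SubjectOutcome(
            subject_id=sid,
            baseline_sz_per_wk=baseline,
            followup1_sz_per_wk=current * (1 + eta),
            followup2_sz_per_wk=current * (1 - eta),
            lead_hemispheres=hemis,
            lead_lobes=lobes,
            stim_enabled=True,
            concurrent_resection=bool(rng_m.random() < 0.32),
        )
        subjects.append(
            SubjectPlan(sid, g, child_seed(design.seed, "sim", sid),
                        couplings, alpha, beta, noiseless, outcome)
        )
    return CohortPlan(design=design, parcellation=parcellation, subjects=subjects)


def simulate_planned_subject(plan: CohortPlan, subject: SubjectPlan) -> RoiTimeSeries:
    ts = simulate_subject(plan.design, plan.parcellation, subject.couplings,
                          subject.sim_seed)
    ts.subject_id = subject.subject_id
    return ts


def iter_cohort(plan: CohortPlan) -> Iterator[tuple[SubjectPlan, RoiTimeSeries]]:
    """Stream (plan, time series) pairs one subject at a time."""
    for subject in plan.subjects:
        yield subject, simulate_planned_subject(plan, subject)


def simulate_cohort(
    design: CohortDesign, parcellation: Parcellation
) -> tuple[list[RoiTimeSeries], list[SubjectOutcome], CohortPlan]:
    """Materialize a whole cohort in memory (desk-scale cohorts only).

    Returns the subjects' time series (controls first), the patients'
    outcomes, and the plan carrying the planted ground truth.
    """
    plan = plan_cohort(design, parcellation)
    series = [simulate_planned_subject(plan, s) for s in plan.subjects]
    outcomes = [s.outcome for s in plan.patients]
    return series, outcomes, plan


def calibrate_outcome_noise(
    design: CohortDesign,
    target_rho: float = 0.45,
    n_cohorts: int = 200,
    seed: int = 0,
) -> float:
    """Outcome noise SD for which the planted dose-response Spearman rho
    (planted alpha coupling vs realized reduction, averaged over cohorts)
    hits ``target_rho``.

    Works at plan level only (no time series), using common random numbers
    across candidate SDs so the objective is monotone in the SD.
    """
    rng = substream(seed, "outcome-noise-cal")
    n_pat = design.n_responders + design.n_nonresponders
    a_max = 0.95 * max_strength("alpha")
    shifts = np.r_[
        np.full(design.n_responders, design.responder_alpha_shift),
        np.full(design.n_nonresponders, design.nonresponder_alpha_shift),
    ]
    alphas = np.clip(
        design.baseline_strength
        + shifts
        + rng.normal(0.0, design.subject_strength_sd, (n_cohorts, n_pat)),
        0.02,
        a_max,
    )
    noiseless = np.clip(
        50.0 + design.outcome_slope * (alphas - design.baseline_strength),
        -100.0, 100.0,
    )
    eps = rng.standard_normal((n_cohorts, n_pat))

    def mean_rho(sd: float) -> float:
        reductions = np.clip(noiseless + sd * eps, -100.0, 100.0)
        rhos = [
            stats.spearmanr(alphas[k], reductions[k]).statistic
            for k in range(n_cohorts)
        ]
        return float(np.mean(rhos))

    if mean_rho(0.5) < target_rho:
        raise ValueError("target rho is above the noiseless dose-response rho")
    return float(optimize.brentq(lambda s: mean_rho(s) - target_rho, 0.5, 500.0,
                                 xtol=0.25))


def with_outcome_noise(design: CohortDesign, sd: float) -> CohortDesign:
    """A copy of the design with a different outcome noise SD."""
    return dataclasses.replace(design, outcome_noise_sd=sd)


def write_cohort(
    plan: CohortPlan,
    directory,
    fmt: str = "hdf5",
    overwrite: bool = False,
) -> dict:
    """Write a planned cohort to disk (streaming one subject at a time).

    Emits one time-series file per subject, ``metadata.csv``,
    ``parcellation.tsv`` and ``ground_truth.json``; existing files abort
    unless ``overwrite`` is set.  Round-trips losslessly through the
    readers in :mod:`rnsfc.io`.
    """
    from pathlib import Path

    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".h5" if fmt == "hdf5" else ".csv"
    paths = {
        "metadata": directory / "metadata.csv",
        "parcellation": directory / "parcellation.tsv",
        "ground_truth": directory / "ground_truth.json",
    }
    ts_paths = {s.subject_id: directory / f"{s.subject_id}{ext}" for s in plan.subjects}
    if not overwrite:
        clashes = [p for p in [*paths.values(), *ts_paths.values()] if p.exists()]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite existing files (pass overwrite=True): "
                f"{[str(p) for p in clashes[:3]]}..."
            )
    for subject, ts in iter_cohort(plan):
        _io.write_timeseries(ts, ts_paths[subject.subject_id], fmt=fmt)
    _io.write_metadata(
        [s.outcome for s in plan.patients],
        [s.subject_id for s in plan.controls],
        paths["metadata"],
    )
    plan.parcellation.to_tsv(paths["parcellation"])
    _io.write_json_report(plan.truth(), paths["ground_truth"])
    return {**paths, "timeseries": ts_paths}
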