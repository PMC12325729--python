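"""Synthetic data with exhaustive ground truth.

Generates ROI fluorescence traces, toy fluorescence movies, and swimming
trajectories that emulate the statistical structure the downstream analyses
assume: a GCaMP6s-like double-exponential impulse response sampled at a few
Hz, spatially compact ensembles whose pairwise correlations decay with
distance, stimulus-evoked excitation and inhibition in configured fractions,
additive vs depressed multisensory combination, drug wash-in baseline
shifts, and tank-swimming with stimulus-evoked diving and light/dark speed
changes.

Every generator is deterministic under a fixed seed, and class assignments
use exact counts (seeded shuffles) so that requested population fractions
are met exactly rather than in expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .types import (
    BehaviorTrack,
    ConfigError,
    GeometryError,
    NeuronGeometry,
    ProtocolError,
    StimulusProtocol,
    TraceMatrix,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "BehaviorParams",
    "calcium_kernel",
    "generate_population",
    "simulate_spontaneous",
    "simulate_evoked",
    "default_evoked_protocol",
    "default_drug_protocol",
    "render_movie",
    "simulate_behavior",
]


@dataclass
class SimConfig:
    """Parameters of the trace simulator.

    Amplitudes are fractional dF/F (0.5 == 50%); the fluorescence baseline
    is ``baseline_f`` arbitrary units so ``noise_sd`` of 2.0 is 2% dF/F of
    per-frame noise. Responder fractions are (excited, inhibited) per
    modality and are realised by exact counts.
    """

    n_neurons: int = 400
    frame_rate: float = 3.0          # Hz; volumetric acquisition runs 2.3-3.4 Hz/plane
    duration_s: float = 600.0        # spontaneous-recording default
    rise_s: float = 0.2              # indicator kernel rise
    decay_s: float = 1.8             # indicator kernel decay (GCaMP6s-like)
    baseline_f: float = 100.0
    noise_sd: float = 2.0            # per-frame additive noise, F units
    # population geometry
    n_ensembles: int = 4
    length_scale_um: float = 15.0
    box_um: tuple = (100.0, 60.0, 80.0)
    # spontaneous activity
    spont_amp: float = 0.3           # fractional dF/F scale of latent signals
    latent_smooth_s: float = 2.0
    cross_coupling: float = -0.3     # off-diagonal ensemble mixing, in [-1, 0];
                                     # negative reproduces cross-cluster anti-correlations
    # evoked responses
    responder_fractions: dict = field(
        default_factory=lambda: {"light": (0.30, 0.10), "vibration": (0.30, 0.10)}
    )
    multimodal_frac: float | None = None  # exact excited-to-both fraction; None = independent assignment
    amp_excited: float = 0.5         # peak dF/F of an excited transient
    amp_inhibited: float = -0.2
    amp_rel_sd: float = 0.2          # per-neuron lognormal amplitude spread
    trial_jitter: float = 0.1        # per-trial multiplicative amplitude jitter
    # multisensory combination: combined amplitude = factor * max(single amplitudes)
    interaction_fractions: dict = field(
        default_factory=lambda: {"additive": 0.2, "depressed": 0.6, "independent": 0.2}
    )
    additive_gain: float = 2.5       # must be >= 2 (at least doubling)
    depression_factor: float = 0.5   # must be < 1
    independent_factor: float = 1.5  # partial summation, interior of [1, 2]
    # drug wash-in
    drug_fractions: dict = field(default_factory=lambda: {"up": 0.0, "down": 0.0})
    amp_drug: float = 0.3
    wash_in_s: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError("n_neurons must be >= 1")
        for name in ("frame_rate", "duration_s", "rise_s", "decay_s", "length_scale_um"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_ensembles < 1:
            raise ConfigError("n_ensembles must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for mod, (fe, fi) in self.responder_fractions.items():
            if not (0 <= fe <= 1 and 0 <= fi <= 1 and fe + fi <= 1):
                raise ConfigError(f"responder fractions for {mod!r} must lie in [0,1] and sum <= 1")
        sfrac = sum(self.interaction_fractions.values())
        if not math.isclose(sfrac, 1.0, abs_tol=1e-9):
            raise ConfigError("interaction_fractions must sum to 1")
        if self.additive_gain < 2:
            raise ConfigError("additive_gain must be >= 2 (at-least-doubling definition)")
        if not 0 < self.depression_factor < 1:
            raise ConfigError("depression_factor must be in (0, 1)")
        if sum(self.drug_fractions.values()) > 1:
            raise ConfigError("drug fractions must sum to <= 1")
        if self.multimodal_frac is not None:
            fl = self.responder_fractions.get("light", (0.0, 0.0))[0]
            fv = self.responder_fractions.get("vibration", (0.0, 0.0))[0]
            if self.multimodal_frac > min(fl, fv) + 1e-12:
                raise ConfigError("multimodal_frac cannot exceed either excited fraction")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass
class GroundTruth:
    """Per-entity truth tables written by every generator.

    ``neurons`` columns (as applicable): neuron_id, ensemble, class_<mod>,
    amp_<mod> (peak dF/F %), ms_mode, drug_effect. ``tracks`` columns:
    track_id, preferred_depth_mm, dive_frac, tau_s, speed_gain.
    """

    neurons: pd.DataFrame | None = None
    tracks: pd.DataFrame | None = None
    config: SimConfig | None = None


def calcium_kernel(frame_rate: float, rise_s: float = 0.2, decay_s: float = 1.8) -> np.ndarray:
    """Peak-normalised double-exponential indicator kernel, sampled at the frame rate."""
    if decay_s <= rise_s:
        raise ConfigError("decay must exceed rise")
    t = np.arange(0.0, 6.0 * decay_s, 1.0 / frame_rate)
    h = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = h.max()
    if peak <= 0:
        raise ConfigError("degenerate kernel")
    return h / peak


def _exact_count_labels(n: int, fractions: dict, rng: np.random.Generator,
                        rest: str = "none") -> np.ndarray:
    """Assign labels by exact counts (largest-remainder rounding), shuffled."""
    names = list(fractions)
    raw = np.array([fractions[k] * n for k in names])
    counts = np.floor(raw).astype(int)
    # distribute only the named classes' rounding remainder; the rest class
    # absorbs whatever the fractions leave unassigned
    short = int(round(raw.sum())) - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        # only top-up classes with positive requested fraction
        for idx in order:
            if short == 0:
                break
            if raw[idx] > 0:
                counts[idx] += 1
                short -= 1
    labels = np.array([rest] * n, dtype=object)
    pool = rng.permutation(n)
    pos = 0
    for name, c in zip(names, counts):
        labels[pool[pos:pos + c]] = name
        pos += c
    return labels


def generate_population(config: SimConfig) -> NeuronGeometry:
    """Place neurons in a 3-D box as spatially compact Gaussian ensembles.

    Ensembles are balanced in size; each is a Gaussian blob of the configured
    length scale around a center drawn uniformly in the box. Depth (z) is
    shifted so the dorsal-most neuron sits at 0.
    """
    config.validate()
    rng = config.rng(salt=1)
    box = np.asarray(config.box_um, dtype=float)
    centers = rng.uniform(0.2 * box, 0.8 * box, size=(config.n_ensembles, 3))
    ensemble = np.repeat(np.arange(config.n_ensembles),
                         -(-config.n_neurons // config.n_ensembles))[: config.n_neurons]
    ensemble = rng.permutation(ensemble)
    pos = centers[ensemble] + rng.normal(0, config.length_scale_um, size=(config.n_neurons, 3))
    pos = np.clip(pos, 0, box)
    pos[:, 2] -= pos[:, 2].min()
    table = pd.DataFrame(
        {
            "neuron_id": np.arange(config.n_neurons),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "ensemble": ensemble,
        }
    )
    return NeuronGeometry(table)


def _ensemble_centers(geometry: NeuronGeometry) -> np.ndarray:
    ens = geometry.ensemble
    pos = geometry.positions
    return np.stack([pos[ens == e].mean(axis=0) for e in np.unique(ens)])


def simulate_spontaneous(geometry: NeuronGeometry, config: SimConfig):
    """Ongoing activity: smoothed latent per ensemble, distance-decaying mixing.

    Each ensemble carries one slow latent signal. A neuron's loading on its
    own ensemble's latent decays exponentially with its distance from the
    ensemble center, which (with additive noise) yields pairwise correlations
    that fall off with anatomical distance. ``cross_coupling`` < 0 mixes a
    sign-flipped copy of foreign latents into each neuron, producing the
    anti-correlations seen across habenular hemispheres/clusters.

    Returns (TraceMatrix, GroundTruth).
    """
    config.validate()
    if geometry.ensemble is None:
        raise ConfigError("geometry must carry ensemble labels")
    rng = config.rng(salt=2)
    n = geometry.n_neurons
    n_frames = int(round(config.duration_s * config.frame_rate))
    ens = np.asarray(geometry.ensemble)
    uniq = np.unique(ens)
    centers = _ensemble_centers(geometry)

    latents = rng.standard_normal((len(uniq), n_frames))
    sigma = config.latent_smooth_s * config.frame_rate
    if sigma > 0:
        latents = gaussian_filter1d(latents, sigma, axis=1, mode="reflect")
    latents /= latents.std(axis=1, keepdims=True)

    # correlate the latents across ensembles (negative coupling produces
    # cross-cluster anti-correlations); symmetric matrix square root keeps
    # the singular cross_coupling = -1 two-ensemble case usable
    k_ens = len(uniq)
    if k_ens > 1 and config.cross_coupling != 0.0:
        cmat = np.full((k_ens, k_ens), config.cross_coupling)
        np.fill_diagonal(cmat, 1.0)
        evals, evecs = np.linalg.eigh(cmat)
        if evals.min() < -1e-9:
            raise ConfigError(
                f"cross_coupling {config.cross_coupling} is not realisable for "
                f"{k_ens} ensembles (correlation matrix not PSD)"
            )
        root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
        latents = root @ latents
        sd = latents.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        latents /= sd

    # each neuron carries its own ensemble's latent, with a loading that
    # decays with its distance from the ensemble center
    pos = geometry.positions
    ens_index = np.searchsorted(uniq, ens)
    d_own = np.linalg.norm(pos - centers[ens_index], axis=1)
    w_own = np.exp(-d_own / config.length_scale_um)
    signal = w_own[:, None] * latents[ens_index]

    kernel = calcium_kernel(config.frame_rate, config.rise_s, config.decay_s)
    signal = fftconvolve(signal, kernel[None, :], axes=1)[:, :n_frames]
    # one global scale so the distance-decaying loadings survive: a neuron at
    # its ensemble center fluctuates with sd ~ spont_amp (fractional dF/F)
    pop_sd = signal.std(axis=1).max()
    if pop_sd > 0:
        signal = config.spont_amp * signal / pop_sd

    f = config.baseline_f * (1.0 + signal)
    if config.noise_sd > 0:
        f = f + rng.normal(0, config.noise_sd, size=f.shape)
    f = np.maximum(f, 1e-3)  # fluorescence stays positive

    traces = TraceMatrix(f, config.frame_rate, geometry.neuron_ids)
    gt = GroundTruth(
        neurons=pd.DataFrame({"neuron_id": geometry.neuron_ids, "ensemble": ens}),
        config=config,
    )
    return traces, gt


def default_evoked_protocol(
    n_repeats: int = 8,
    isi_s: float = 60.0,
    block_gap_s: float = 240.0,
    modalities: tuple = ("vibration", "light", "both"),
    start_s: float = 30.0,
    stim_duration_s: float = 2.0,
) -> StimulusProtocol:
    """Blocked sensory protocol: per modality, repeats at a fixed ISI,
    blocks separated by a rest gap (defaults follow the stimulation design:
    8 repeats, 60 s ISI, 4 min between condition sets)."""
    rows = []
    t = start_s
    for m in modalities:
        for _ in range(n_repeats):
            rows.append({"onset_s": t, "duration_s": stim_duration_s, "modality": m})
            t += isi_s
        t += block_gap_s - isi_s
    return StimulusProtocol(pd.DataFrame(rows))


def default_drug_protocol(onset_min: float = 13.0, offset_min: float = 18.0) -> StimulusProtocol:
    """Drug wash-in window as a pair of drug_on/drug_off markers (the
    antagonist evaluation window runs minute 13 to 18 of the experiment)."""
    rows = [
        {"onset_s": onset_min * 60.0, "duration_s": 0.0, "modality": "drug_on"},
        {"onset_s": offset_min * 60.0, "duration_s": 0.0, "modality": "drug_off"},
    ]
    return StimulusProtocol(pd.DataFrame(rows))


def protocol_duration(protocol: StimulusProtocol, pad_s: float = 60.0) -> float:
    ev = protocol.events
    return float((ev["onset_s"] + ev["duration_s"]).max() + pad_s)


def _assign_classes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_neurons
    cols = {"neuron_id": np.arange(n)}
    mods = list(config.responder_fractions)
    if config.multimodal_frac is not None and {"light", "vibration"} <= set(mods):
        fl, il = config.responder_fractions["light"]
        fv, iv = config.responder_fractions["vibration"]
        mm = config.multimodal_frac
        joint = _exact_count_labels(
            n,
            {"M": mm, "L": fl - mm, "V": fv - mm},
            rng,
            rest="rest",
        )
        cl = np.where(np.isin(joint, ["M", "L"]), "excited", "none").astype(object)
        cv = np.where(np.isin(joint, ["M", "V"]), "excited", "none").astype(object)
        # inhibited drawn from the remaining pool, exact counts
        for frac_inh, arr in ((il, cl), (iv, cv)):
            pool = np.flatnonzero(arr == "none")
            k = int(round(frac_inh * n))
            pick = rng.permutation(pool)[:k]
            arr[pick] = "inhibited"
        cols["class_light"], cols["class_vibration"] = cl, cv
        other_mods = [m for m in mods if m not in ("light", "vibration")]
    else:
        other_mods = mods
    for m in other_mods:
        fe, fi = config.responder_fractions[m]
        cols[f"class_{m}"] = _exact_count_labels(n, {"excited": fe, "inhibited": fi}, rng)
    cols["ms_mode"] = _exact_count_labels(n, config.interaction_fractions, rng, rest="independent")
    cols["drug_effect"] = _exact_count_labels(n, config.drug_fractions, rng)
    return pd.DataFrame(cols)


def simulate_evoked(geometry: NeuronGeometry, protocol: StimulusProtocol, config: SimConfig,
                    duration_s: float | None = None):
    """Stimulus-evoked traces with per-neuron ground-truth classes.

    Excited neurons receive a positive kernel-convolved transient at each
    matching onset, inhibited neurons a negative deflection. On combined
    (``both``) events the amplitude is ``factor * max(single amplitudes)``
    with the factor set by the neuron's multisensory mode: additive
    (>= 2, super-additive by construction), depressed (< 1), independent
    (between 1 and 2, i.e. partial summation). Drug markers apply a ramped
    baseline shift to drug-affected neurons.

    With ``duration_s`` unset the recording is sized to fit the protocol
    (at least ``config.duration_s``); an explicit duration is enforced and
    events outside it raise a protocol error.

    Returns (TraceMatrix, GroundTruth).
    """
    config.validate()
    rng = config.rng(salt=3)
    n = config.n_neurons
    if geometry.n_neurons != n:
        raise ConfigError("geometry size does not match config.n_neurons")
    duration = (max(config.duration_s, protocol_duration(protocol))
                if duration_s is None else float(duration_s))
    n_frames = int(round(duration * config.frame_rate))
    protocol.check_within(duration)

    truth = _assign_classes(config, rng)
    if geometry.ensemble is not None:
        truth["ensemble"] = np.asarray(geometry.ensemble)

    # per-neuron peak amplitudes (fractional dF/F), lognormal spread
    amps: dict[str, np.ndarray] = {}
    for m in config.responder_fractions:
        cls = truth[f"class_{m}"].to_numpy()
        spread = rng.lognormal(mean=0.0, sigma=config.amp_rel_sd, size=n)
        a = np.zeros(n)
        a[cls == "excited"] = config.amp_excited * spread[cls == "excited"]
        a[cls == "inhibited"] = config.amp_inhibited * spread[cls == "inhibited"]
        amps[m] = a
        truth[f"amp_{m}"] = 100.0 * a  # stored in percent

    mode_factor = {
        "additive": config.additive_gain,
        "depressed": config.depression_factor,
        "independent": config.independent_factor,
    }
    factors = truth["ms_mode"].map(mode_factor).to_numpy(dtype=float)

    signal = np.zeros((n, n_frames))
    fr = config.frame_rate
    for _, ev in protocol.events.iterrows():
        m = ev["modality"]
        if m in ("drug_on", "drug_off"):
            continue
        if m == "both":
            a_l = amps.get("light", np.zeros(n))
            a_v = amps.get("vibration", np.zeros(n))
            a = factors * np.maximum(a_l, a_v)
        elif m in amps:
            a = amps[m]
        else:
            continue
        if config.trial_jitter > 0:
            a = a * np.maximum(0.0, 1.0 + config.trial_jitter * rng.standard_normal(n))
        idx = int(np.ceil(ev["onset_s"] * fr - 1e-9))
        if idx < n_frames:
            signal[:, idx] += a

    kernel = calcium_kernel(fr, config.rise_s, config.decay_s)
    signal = fftconvolve(signal, kernel[None, :], axes=1)[:, :n_frames]

    # drug wash-in: ramped baseline shift between drug_on and drug_off
    on = protocol.onsets("drug_on")
    off = protocol.onsets("drug_off")
    if on.size:
        t = np.arange(n_frames) / fr
        t_on = on[0]
        t_off = off[0] if off.size else duration
        ramp = np.clip((t - t_on) / config.wash_in_s, 0.0, 1.0)
        ramp[t >= t_off] = np.clip(
            1.0 - (t[t >= t_off] - t_off) / config.wash_in_s, 0.0, 1.0
        )
        direction = truth["drug_effect"].map({"up": 1.0, "down": -1.0, "none": 0.0})
        shift = direction.to_numpy(dtype=float)[:, None] * config.amp_drug * ramp[None, :]
        signal = signal + shift

    f = config.baseline_f * (1.0 + signal)
    if config.noise_sd > 0:
        f = f + rng.normal(0, config.noise_sd, size=f.shape)
    f = np.maximum(f, 1e-3)
    traces = TraceMatrix(f, fr, geometry.neuron_ids)
    truth["neuron_id"] = geometry.neuron_ids
    return traces, GroundTruth(neurons=truth, config=config)


def render_movie(
    traces: TraceMatrix,
    frame_shape: tuple = (64, 64),
    roi_halfwidth: int = 1,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
):
    """Paint each neuron's trace uniformly over a small square ROI.

    ROIs are laid out on a regular grid (disjoint by construction); labels
    in the returned mask image are ``neuron index + 1`` (0 = background),
    aligned with the trace row order.

    Returns (movie ``(n_frames, H, W)``, label image ``(H, W)``).
    """
    h, w = frame_shape
    side = 2 * roi_halfwidth + 1
    cell = side + 1
    ny, nx = h // cell, w // cell
    if ny * nx < traces.n_neurons:
        raise GeometryError(
            f"frame {frame_shape} fits {ny * nx} ROIs of side {side}, need {traces.n_neurons}"
        )
    labels = np.zeros((h, w), dtype=int)
    for i in range(traces.n_neurons):
        r, c = divmod(i, nx)
        r0, c0 = r * cell, c * cell
        labels[r0:r0 + side, c0:c0 + side] = i + 1
    movie = np.zeros((traces.n_frames, h, w), dtype=float)
    flat = labels.ravel()
    for i in range(traces.n_neurons):
        mask = flat == i + 1
        if not mask.any():
            raise GeometryError(f"neuron {i} received an empty mask")
        movie.reshape(traces.n_frames, -1)[:, mask] = traces.data[i][:, None]
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        movie = movie + rng.normal(0, pixel_noise_sd, size=movie.shape)
    return movie, labels


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorParams:
    """Swimming-simulation parameters; per-assay defaults via :meth:`for_assay`.

    Depth follows a mean-reverting walk toward a set-point. A vibration
    drops the set-point by ``dive_frac`` of the preferred depth, holds it
    down for ``hold_s`` (the period over which evoked diving is sustained),
    then releases it with exponential recovery time constant ``tau_s``.
    Dark phases multiply the target swim speed by ``dark_speed_gain``.
    """

    arena_w_mm: float = 115.0
    arena_h_mm: float = 115.0
    sample_rate_hz: float = 10.0
    duration_s: float = 1800.0
    view: str = "side"
    preferred_depth_mm: float = 40.0
    depth_relax_per_s: float = 5.0       # position tracks the set-point fast
    depth_noise_mm: float = 3.0          # per-sqrt(s) diffusion
    dive_frac: float = 0.5
    hold_s: float = 30.0
    tau_s: float = 30.0
    explore_tau_s: float = 300.0         # novel-tank upward exploration
    entry_depth_mm: float = 5.0
    base_speed_mm_s: float = 20.0
    speed_noise_frac: float = 0.3
    dark_speed_gain: float = 2.0
    heading_diffusion: float = 2.0       # rad / sqrt(s)
    # event schedule
    n_vibrations: int = 15
    vib_isi_s: float = 60.0
    vib_baseline_s: float = 240.0
    ld_habituation_s: float = 300.0
    ld_phase_s: float = 300.0
    ld_cycles: int = 3

    @classmethod
    def for_assay(cls, assay: str) -> "BehaviorParams":
        if assay == "novel_tank":
            return cls(duration_s=1800.0)
        if assay == "vibration":
            p = cls(arena_w_mm=100.0, arena_h_mm=115.0)
            p.duration_s = p.vib_baseline_s + p.n_vibrations * p.vib_isi_s + 240.0
            return p
        if assay == "light_dark":
            p = cls(arena_w_mm=35.0, arena_h_mm=35.0, view="top")
            p.duration_s = p.ld_habituation_s + 2 * p.ld_cycles * p.ld_phase_s
            return p
        raise ConfigError(f"unknown assay {assay!r}")


def _behavior_events(assay: str, p: BehaviorParams) -> pd.DataFrame:
    rows = []
    if assay == "novel_tank":
        rows.append({"time_s": 0.0, "kind": "tank_entry"})
    elif assay == "vibration":
        for i in range(p.n_vibrations):
            rows.append({"time_s": p.vib_baseline_s + i * p.vib_isi_s, "kind": "vibration"})
    elif assay == "light_dark":
        t = p.ld_habituation_s
        for _ in range(p.ld_cycles):
            rows.append({"time_s": t, "kind": "dark_on"})
            t += p.ld_phase_s
            rows.append({"time_s": t, "kind": "light_on"})
            t += p.ld_phase_s
    ev = pd.DataFrame(rows, columns=["time_s", "kind"])
    if len(ev) and (ev["time_s"] > p.duration_s).any():
        raise ProtocolError("behavior events fall outside the recording duration")
    return ev


def simulate_behavior(assay: str, params: BehaviorParams | None = None, seed: int = 0,
                      track_id: int = 0):
    """Simulate one swimming track for the given assay.

    Returns (BehaviorTrack, GroundTruth) where the ground truth records the
    preferred depth, dive magnitude, recovery time constant and dark-phase
    speed gain of this track.
    """
    p = params if params is not None else BehaviorParams.for_assay(assay)
    if p.duration_s <= 0 or p.arena_w_mm <= 0 or p.arena_h_mm <= 0:
        raise ConfigError("arena dimensions and duration must be positive")
    events = _behavior_events(assay, p)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17, track_id]))
    dt = 1.0 / p.sample_rate_hz
    nt = int(round(p.duration_s * p.sample_rate_hz)) + 1
    t = np.arange(nt) * dt

    # depth set-point over time
    setpoint = np.full(nt, p.preferred_depth_mm)
    if assay == "novel_tank":
        setpoint = p.preferred_depth_mm + (p.entry_depth_mm - p.preferred_depth_mm) * np.exp(
            -t / p.explore_tau_s
        )
    for ts in events.loc[events["kind"] == "vibration", "time_s"]:
        rel = t - float(ts)
        drop = np.zeros(nt)
        in_hold = (rel >= 0) & (rel < p.hold_s)
        after = rel >= p.hold_s
        drop[in_hold] = 1.0
        drop[after] = np.exp(-(rel[after] - p.hold_s) / p.tau_s)
        setpoint = setpoint - p.dive_frac * p.preferred_depth_mm * drop
    setpoint = np.clip(setpoint, 1.0, p.arena_h_mm - 1.0)

    # target speed over time (dark phases faster)
    speed_target = np.full(nt, p.base_speed_mm_s)
    dark = np.zeros(nt, dtype=bool)
    for _, ev in events.iterrows():
        if ev["kind"] == "dark_on":
            dark[t >= ev["time_s"]] = True
        elif ev["kind"] == "light_on":
            dark[t >= ev["time_s"]] = False
    speed_target[dark] *= p.dark_speed_gain

    x = np.empty(nt)
    y = np.empty(nt)
    if p.view == "side":
        # horizontal: reflected random walk at the target speed;
        # vertical: fast mean reversion to the depth set-point
        y[0] = setpoint[0]
        x[0] = p.arena_w_mm / 2
        sgn = 1.0
        for i in range(1, nt):
            k = p.depth_relax_per_s
            noise = p.depth_noise_mm * math.sqrt(dt) * rng.standard_normal()
            y[i] = y[i - 1] + k * (setpoint[i] - y[i - 1]) * dt + noise
            if rng.random() < 0.05:
                sgn = -sgn
            v = speed_target[i] * max(0.0, 1.0 + p.speed_noise_frac * rng.standard_normal())
            x[i] = x[i - 1] + sgn * v * dt
            if x[i] < 0:
                x[i], sgn = -x[i], -sgn
            if x[i] > p.arena_w_mm:
                x[i], sgn = 2 * p.arena_w_mm - x[i], -sgn
        y = np.clip(y, 0.0, p.arena_h_mm)
    else:
        # top view: heading random walk, speed set by light condition
        x[0], y[0] = p.arena_w_mm / 2, p.arena_h_mm / 2
        theta = rng.uniform(0, 2 * np.pi)
        for i in range(1, nt):
            theta += p.heading_diffusion * math.sqrt(dt) * rng.standard_normal()
            v = speed_target[i] * max(0.0, 1.0 + p.speed_noise_frac * rng.standard_normal())
            x[i] = x[i - 1] + v * dt * math.cos(theta)
            y[i] = y[i - 1] + v * dt * math.sin(theta)
            if x[i] < 0:
                x[i], theta = -x[i], np.pi - theta
            if x[i] > p.arena_w_mm:
                x[i], theta = 2 * p.arena_w_mm - x[i], np.pi - theta
            if y[i] < 0:
                y[i], theta = -y[i], -theta
            if y[i] > p.arena_h_mm:
                y[i], theta = 2 * p.arena_h_mm - y[i], -theta

    track = BehaviorTrack(
        t_s=t, x_mm=x, y_mm=y,
        arena_w_mm=p.arena_w_mm, arena_h_mm=p.arena_h_mm,
        view=p.view, events=events, track_id=track_id,
    )
    gt = GroundTruth(
        tracks=pd.DataFrame(
            [
                {
                    "track_id": track_id,
                    "assay": assay,
                    "preferred_depth_mm": p.preferred_depth_mm,
                    "dive_frac": p.dive_frac,
                    "hold_s": p.hold_s,
                    "tau_s": p.tau_s,
                    "speed_gain": p.dark_speed_gain,
                }
            ]
        )
    )
    return track, gt
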