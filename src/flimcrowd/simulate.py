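"""Synthetic data generators for the full analysis pipeline.

Every generator is the generative inverse of one of the package's fitting
operations: photon-level TCSPC decays (multi-exponential, Gaussian IRF,
repetition-window wrap), FLIM scenes with per-pixel Poisson photon budgets,
two-species Brownian diffusion through a 3D Gaussian focus with optional
photobleaching, polarized anisotropy decay pairs, toy beta-barrel-like
trajectories with a breathing pocket, and lifetime-vs-FVO calibration tables.

All randomness flows from one explicit integer seed per call; no global RNG
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import DecayHistogram, InstrumentResponse

__all__ = [
    "DecaySimSpec",
    "FlimSceneSpec",
    "CondensateSpec",
    "FcsSimSpec",
    "DiffusingSpecies",
    "ToyTrajectorySpec",
    "simulate_tcspc_decay",
    "simulate_flim_scene",
    "simulate_fcs_trajectory",
    "simulate_anisotropy_decays",
    "generate_toy_trajectory",
    "generate_calibration_table",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass
class DecaySimSpec:
    """Photon-level TCSPC decay simulation parameters.

    Defaults follow a 100 ps FWHM pulsed source at 20 MHz repetition rate
    (50 ns window).
    """

    component_lifetimes: Sequence[float]
    component_amplitudes: Sequence[float]
    irf_fwhm: float = 0.1
    irf_t0: float = 2.0
    repetition_window: float = 50.0
    n_photons: int = 100_000
    bin_width: float = 50.0 / 512
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        taus = np.asarray(self.component_lifetimes, dtype=float)
        amps = np.asarray(self.component_amplitudes, dtype=float)
        _require(taus.size > 0, "component_lifetimes", "must be non-empty")
        _require(bool(np.all(taus > 0)), "component_lifetimes", "must be positive")
        _require(bool(np.all(amps >= 0)), "component_amplitudes", "must be nonnegative")
        _require(float(amps.sum()) > 0, "component_amplitudes", "must sum to > 0")
        _require(self.irf_fwhm >= 0, "irf_fwhm", "must be nonnegative")
        _require(
            self.repetition_window > float(taus.max()),
            "repetition_window",
            "must exceed the longest lifetime",
        )
        _require(self.n_photons >= 1, "n_photons", "must be >= 1")
        _require(self.bin_width > 0, "bin_width", "must be positive")
        _require(self.background_rate >= 0, "background_rate", "must be nonnegative")


def _draw_decay_times(
    rng: np.random.Generator,
    n: int,
    taus: np.ndarray,
    amps: np.ndarray,
    irf_fwhm: float,
    irf_t0: float,
    window: float,
) -> np.ndarray:
    comp = rng.choice(taus.size, size=n, p=amps / amps.sum())
    t = rng.exponential(taus[comp])
    if irf_fwhm > 0:
        sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        t = t + rng.normal(0.0, sigma, size=n)
    return np.mod(t + irf_t0, window)


def simulate_tcspc_decay(spec: DecaySimSpec) -> DecayHistogram:
    """Simulate a TCSPC histogram photon by photon.

    Each photon draws a decay component by amplitude weight, an exponential
    delay, Gaussian IRF jitter, and is wrapped modulo the repetition window.
    Background counts are uniform over the window.
    """
    rng = np.random.default_rng(spec.seed)
    taus = np.asarray(spec.component_lifetimes, dtype=float)
    amps = np.asarray(spec.component_amplitudes, dtype=float)
    times = _draw_decay_times(
        rng, spec.n_photons, taus, amps, spec.irf_fwhm, spec.irf_t0, spec.repetition_window
    )
    hist = DecayHistogram.from_times(times, spec.bin_width, spec.repetition_window)
    if spec.background_rate > 0:
        bg = rng.poisson(spec.background_rate, size=hist.counts.shape[0])
        hist = DecayHistogram(hist.bin_edges, hist.counts + bg, channel=hist.channel)
    return hist


@dataclass
class CondensateSpec:
    """A disk condensate: center (row, col), radius (px) and its lifetime
    field, either a single value or per-subdomain values split along columns."""

    center: tuple[float, float]
    radius: float
    lifetimes: Sequence[float] = (1.2,)
    split_fractions: Sequence[float] | None = None

    def __post_init__(self) -> None:
        _require(self.radius > 0, "radius", "must be positive")
        _require(
            bool(np.all(np.asarray(self.lifetimes) > 0)),
            "lifetimes",
            "must be positive",
        )
        if self.split_fractions is not None:
            fr = np.asarray(self.split_fractions, dtype=float)
            _require(
                fr.size == len(self.lifetimes) and abs(fr.sum() - 1.0) < 1e-9,
                "split_fractions",
                "must give one fraction per lifetime, summing to 1",
            )


@dataclass
class FlimSceneSpec:
    """Scene specification for a simulated FLIM acquisition."""

    image_shape: tuple[int, int] = (64, 64)
    condensates: Sequence[CondensateSpec] = ()
    background_lifetime: float = 1.5
    photon_budget: float | np.ndarray = 100.0
    n_frames: int = 5
    irf_fwhm: float = 0.1
    irf_t0: float = 2.0
    repetition_window: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.background_lifetime > 0, "background_lifetime", "must be positive")
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        budget = np.asarray(self.photon_budget, dtype=float)
        _require(bool(np.all(budget >= 0)), "photon_budget", "must be nonnegative")
        for c in self.condensates:
            r, ccol = c.center
            _require(
                0 <= r < self.image_shape[0] and 0 <= ccol < self.image_shape[1],
                "condensates",
                "centers must lie within image bounds",
            )

    def ground_truth_map(self) -> np.ndarray:
        """Per-pixel true lifetime map; overlapping condensates: later wins."""
        h, w = self.image_shape
        rows, cols = np.mgrid[0:h, 0:w]
        truth = np.full((h, w), self.background_lifetime, dtype=float)
        for c in self.condensates:
            inside = (rows - c.center[0]) ** 2 + (cols - c.center[1]) ** 2 <= c.radius**2
            lifes = np.asarray(c.lifetimes, dtype=float)
            if lifes.size == 1:
                truth[inside] = lifes[0]
            else:
                # split the disk into column bands, one per value; band widths
                # follow split_fractions (equal by default)
                fr = (
                    np.full(lifes.size, 1.0 / lifes.size)
                    if c.split_fractions is None
                    else np.asarray(c.split_fractions, dtype=float)
                )
                cum = np.concatenate([[0.0], np.cumsum(fr)])
                cmin, cmax = c.center[1] - c.radius, c.center[1] + c.radius
                rel = (cols - cmin) / (cmax - cmin + 1e-12)
                band = np.clip(
                    np.searchsorted(cum, rel, side="right") - 1, 0, lifes.size - 1
                )
                truth[inside] = lifes[band[inside]]
        return truth


def simulate_flim_scene(spec: FlimSceneSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a photon-record scan stream plus its ground-truth map.

    Returns a DataFrame with columns frame, x, y, channel, microtime_ns (one
    row per photon) and the true per-pixel lifetime map.  Per-pixel photon
    counts are Poisson with the pixel's budget split across frames.
    """
    rng = np.random.default_rng(spec.seed)
    truth = spec.ground_truth_map()
    h, w = spec.image_shape
    budget = np.broadcast_to(np.asarray(spec.photon_budget, dtype=float), (h, w))
    frames_out, xs, ys, times = [], [], [], []
    for f in range(spec.n_frames):
        counts = rng.poisson(budget / spec.n_frames)
        total = int(counts.sum())
        if total == 0:
            continue
        yy, xx = np.nonzero(counts)
        reps = counts[yy, xx]
        y_idx = np.repeat(yy, reps)
        x_idx = np.repeat(xx, reps)
        tau = truth[y_idx, x_idx]
        t = rng.exponential(tau)
        if spec.irf_fwhm > 0:
            sigma = spec.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            t = t + rng.normal(0.0, sigma, size=t.shape)
        t = np.mod(t + spec.irf_t0, spec.repetition_window)
        frames_out.append(np.full(total, f, dtype=np.int32))
        xs.append(x_idx.astype(np.int32))
        ys.append(y_idx.astype(np.int32))
        times.append(t)
    if not times:
        stream = pd.DataFrame(
            {
                "frame": np.array([], dtype=np.int32),
                "x": np.array([], dtype=np.int32),
                "y": np.array([], dtype=np.int32),
                "channel": np.array([], dtype=np.int32),
                "microtime_ns": np.array([], dtype=float),
            }
        )
        return stream, truth
    stream = pd.DataFrame(
        {
            "frame": np.concatenate(frames_out),
            "x": np.concatenate(xs),
            "y": np.concatenate(ys),
            "channel": np.zeros(sum(len(t) for t in times), dtype=np.int32),
            "microtime_ns": np.concatenate(times),
        }
    )
    return stream, truth


@dataclass
class DiffusingSpecies:
    """One diffusing species: D in um^2/s, number fraction, brightness in
    counts/s per molecule at the focus center."""

    diffusion_coefficient: float
    fraction: float
    brightness: float

    def __post_init__(self) -> None:
        _require(self.diffusion_coefficient >= 0, "diffusion_coefficient", "must be >= 0")
        _require(self.fraction >= 0, "fraction", "must be >= 0")
        _require(self.brightness >= 0, "brightness", "must be >= 0")


@dataclass
class FcsSimSpec:
    """Brownian-dynamics FCS simulation in a periodic box.

    The observation profile is a 3D Gaussian W(r) = exp(-2(x^2+y^2)/w_xy^2 -
    2 z^2/w_z^2).  ``mean_occupancy`` sets the average number of molecules in
    the effective focal volume pi^{3/2} w_xy^2 w_z.  ``bleach_rate_per_excursion``
    is the excitation-driven irreversible bleaching hazard (1/s) at focus
    center; the per-step hazard scales with W(r).
    """

    species: Sequence[DiffusingSpecies]
    focus_waists: tuple[float, float] = (0.25, 1.25)
    box_size: float = 5.0
    duration: float = 120.0
    bin_time: float = 1e-4
    mean_occupancy: float = 5.0
    bleach_rate_per_excursion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.bin_time > 0, "bin_time", "must be positive")
        fr = np.array([s.fraction for s in self.species], dtype=float)
        _require(bool(np.all(fr >= 0)), "species", "fractions must be >= 0")
        _require(abs(float(fr.sum()) - 1.0) < 1e-9, "species", "fractions must sum to 1")
        _require(
            self.duration / self.bin_time >= 1e3,
            "duration",
            "must yield at least 1e3 bins",
        )
        _require(self.focus_waists[0] > 0 and self.focus_waists[1] > 0, "focus_waists", "must be positive")
        _require(self.box_size > 2 * self.focus_waists[0], "box_size", "must exceed the focus")

    @property
    def diffusion_times(self) -> np.ndarray:
        """Ground-truth diffusion times tau_D = w_xy^2 / (4 D) in seconds."""
        return np.array(
            [
                self.focus_waists[0] ** 2 / (4.0 * s.diffusion_coefficient)
                if s.diffusion_coefficient > 0
                else np.inf
                for s in self.species
            ]
        )


def simulate_fcs_trajectory(
    spec: FcsSimSpec, chunk_bins: int = 20_000
) -> tuple[np.ndarray, dict]:
    """Simulate a binned fluorescence intensity trajectory.

    Returns (counts per bin, ground-truth dict with diffusion times,
    particle numbers and the focal-volume occupancy).
    """
    rng = np.random.default_rng(spec.seed)
    n_bins = int(round(spec.duration / spec.bin_time))
    w_xy, w_z = spec.focus_waists
    v_eff = np.pi**1.5 * w_xy**2 * w_z
    box = spec.box_size
    conc = spec.mean_occupancy / v_eff
    n_total = max(int(round(conc * box**3)), 1)
    fractions = np.array([s.fraction for s in spec.species])
    n_per = rng.multinomial(n_total, fractions)
    rate = np.zeros(n_bins)
    for s, n_p in zip(spec.species, n_per):
        if n_p == 0 or s.brightness == 0:
            continue
        pos = rng.uniform(-box / 2.0, box / 2.0, size=(n_p, 3))
        alive = np.ones(n_p, dtype=bool)
        step_sd = np.sqrt(2.0 * s.diffusion_coefficient * spec.bin_time)
        start = 0
        while start < n_bins:
            stop = min(start + chunk_bins, n_bins)
            m = stop - start
            steps = rng.normal(0.0, step_sd, size=(m, n_p, 3)) if step_sd > 0 else None
            for i in range(m):
                if steps is not None:
                    pos += steps[i]
                    pos = (pos + box / 2.0) % box - box / 2.0
                wgt = np.exp(
                    -2.0 * (pos[:, 0] ** 2 + pos[:, 1] ** 2) / w_xy**2
                    - 2.0 * pos[:, 2] ** 2 / w_z**2
                )
                wgt = wgt * alive
                rate[start + i] += s.brightness * wgt.sum()
                if spec.bleach_rate_per_excursion > 0:
                    p_bleach = spec.bleach_rate_per_excursion * wgt * spec.bin_time
                    alive &= rng.random(n_p) >= p_bleach
            start = stop
    counts = rng.poisson(rate * spec.bin_time)
    truth = {
        "diffusion_times": spec.diffusion_times,
        "n_particles": n_per,
        "mean_occupancy": spec.mean_occupancy,
        "bin_time": spec.bin_time,
    }
    return counts, truth


def simulate_anisotropy_decays(
    r0: float,
    rotational_components: Sequence[tuple[float, float]],
    lifetime: float,
    g_factor: float = 1.0,
    n_photons: int = 1_000_000,
    seed: int = 0,
    irf_fwhm: float = 0.0,
    irf_t0: float = 0.0,
    repetition_window: float = 50.0,
    bin_width: float = 50.0 / 1024,
) -> tuple[DecayHistogram, DecayHistogram]:
    """Simulate a polarized decay pair with rotational depolarization.

    I_par(t) ~ I(t) [1 + 2 r(t)], I_perp(t) ~ I(t) [1 - r(t)] / G with
    r(t) = r0 * sum_i w_i exp(-t / theta_i); counts are Poisson per bin with
    the pair's total expectation normalized to ``n_photons``.  ``theta_i``
    of ``numpy.inf`` is the frozen-rotation limit.
    """
    if not 0 < r0 <= 0.4:
        raise ValueError("r0 exceeds theoretical limit (must be in (0, 0.4])")
    comps = [(float(th), float(wg)) for th, wg in rotational_components]
    weights = np.array([wg for _, wg in comps])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("rotational component weights must sum to 1")
    if g_factor <= 0:
        raise ValueError("g_factor must be positive")
    rng = np.random.default_rng(seed)
    n_bins = int(round(repetition_window / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    t = centers
    r_t = r0 * sum(
        wg * (np.ones_like(t) if np.isinf(th) else np.exp(-t / th)) for th, wg in comps
    )
    intensity = np.exp(-t / lifetime)
    par = intensity * (1.0 + 2.0 * r_t)
    perp = intensity * (1.0 - r_t) / g_factor
    if irf_fwhm > 0 or irf_t0 > 0:
        irf = InstrumentResponse(fwhm=irf_fwhm, t0=irf_t0)
        k = irf.kernel(edges)
        par = np.real(np.fft.ifft(np.fft.fft(par) * np.fft.fft(k)))
        perp = np.real(np.fft.ifft(np.fft.fft(perp) * np.fft.fft(k)))
    scale = n_photons / (par.sum() + perp.sum())
    par_counts = rng.poisson(par * scale)
    perp_counts = rng.poisson(perp * scale)
    return (
        DecayHistogram(edges, par_counts, channel="parallel"),
        DecayHistogram(edges, perp_counts, channel="perpendicular"),
    )


@dataclass
class ToyTrajectorySpec:
    """Toy beta-barrel-like residue trajectory with a breathing pocket.

    Residue C-alpha sites sit on a cylindrical lattice; pocket residues are
    displaced radially outward by the per-state expansion offset plus
    isotropic Gaussian thermal noise.
    """

    n_residues: int = 60
    n_frames: int = 40
    pocket_residue_indices: Sequence[int] = ()
    pocket_expansion_per_state: Sequence[float] = (0.0,)
    state_sequence: Sequence[int] | None = None
    thermal_noise_sd: float = 0.0
    barrel_radius: float = 8.0
    residues_per_ring: int = 12
    ring_spacing: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_frames >= 4, "n_frames", "must be >= 4")
        _require(self.n_residues >= 1, "n_residues", "must be >= 1")
        idx = np.asarray(sorted(self.pocket_residue_indices), dtype=int)
        _require(
            idx.size == 0 or (idx.min() >= 0 and idx.max() < self.n_residues),
            "pocket_residue_indices",
            "must be a subset of residue indices",
        )
        _require(self.thermal_noise_sd >= 0, "thermal_noise_sd", "must be >= 0")
        if self.state_sequence is not None:
            states = np.asarray(self.state_sequence, dtype=int)
            _require(states.size == self.n_frames, "state_sequence", "one state per frame")
            _require(
                states.min() >= 0
                and states.max() < len(self.pocket_expansion_per_state),
                "state_sequence",
                "states must index pocket_expansion_per_state",
            )


def generate_toy_trajectory(spec: ToyTrajectorySpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate frames of C-alpha coordinates on a cylindrical barrel lattice.

    Returns (coords of shape (n_frames, n_residues, 3) in Angstrom, residue
    metadata DataFrame with residue_index / is_pocket / base coordinates).
    Deterministic for a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    i = np.arange(spec.n_residues)
    ang = 2.0 * np.pi * (i % spec.residues_per_ring) / spec.residues_per_ring
    ring = i // spec.residues_per_ring
    base = np.stack(
        [
            spec.barrel_radius * np.cos(ang),
            spec.barrel_radius * np.sin(ang),
            ring * spec.ring_spacing,
        ],
        axis=1,
    )
    radial = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
    pocket = np.zeros(spec.n_residues, dtype=bool)
    pocket[np.asarray(list(spec.pocket_residue_indices), dtype=int)] = True
    states = (
        np.zeros(spec.n_frames, dtype=int)
        if spec.state_sequence is None
        else np.asarray(spec.state_sequence, dtype=int)
    )
    offsets = np.asarray(spec.pocket_expansion_per_state, dtype=float)[states]
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    coords[:, pocket, :] += offsets[:, None, None] * radial[None, pocket, :]
    if spec.thermal_noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.thermal_noise_sd, size=coords.shape)
    meta = pd.DataFrame(
        {
            "residue_index": i,
            "is_pocket": pocket,
            "x0": base[:, 0],
            "y0": base[:, 1],
            "z0": base[:, 2],
        }
    )
    return coords, meta


def generate_calibration_table(
    onset_fvo: float,
    plateau_lifetime: float,
    slope: float,
    fvo_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Lifetime-vs-FVO calibration table: flat plateau, then linear decline.

    lifetime(f) = plateau for f <= onset, plateau + slope * (f - onset)
    above, plus Gaussian noise.  ``slope`` is in ns per % FVO (negative for
    the crowding-quenched decline).
    """
    grid = np.asarray(fvo_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("fvo_grid must be strictly increasing")
    if grid.min() < 0 or grid.max() > 100:
        raise ValueError("fvo_grid values must lie in [0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    life = np.where(
        grid <= onset_fvo,
        plateau_lifetime,
        plateau_lifetime + slope * (grid - onset_fvo),
    )
    if noise_sd > 0:
        life = life + rng.normal(0.0, noise_sd, size=grid.shape)
    return pd.DataFrame({"fvo_percent": grid, "mean_lifetime_ns": life})
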