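"""Ground-truth-known synthetic inputs for the analysis pipeline.

Generators emulating the structure (not the optics) of single-cell aging
data: mother-lineage traces sampled on a 10-min grid with budding events, a
planted senescence entry point and fluorescence channels with Gaussian
noise; 2D cell images with planted nuclei and foci; and exponential FLIP
decay traces with known half-life.  Every generator is a pure function of
its specification and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import LineageTrace
from .imaging import CellImage, FlipTrace

__all__ = [
    "CohortSpec",
    "gen_cohort_traces",
    "gen_cell_image",
    "gen_flip_trace",
]


@dataclass
class CohortSpec:
    """Specification of a synthetic mother-cell cohort.

    Lifespans are drawn from a truncated normal (>= 1 generation); young
    interdivision times are lognormal around ``young_mean_min``; from the
    planted SEP (``sep_offset`` generations before death) onward, durations
    are multiplied by ``post_sep_multiplier``.  Fluorescence channels are
    ``name -> (baseline, trend per min, noise SD)``.  A per-cell foci-onset
    indicator is coupled to death within ``window_min`` with the planted
    odds ratio ``foci_death_or``.
    """

    n: int = 50
    lifespan_mean: float = 30.0
    lifespan_sd: float = 8.0
    young_mean_min: float = 90.0
    young_cv: float = 0.08
    sep_offset: int = 3
    post_sep_multiplier: float = 2.5
    sampling_interval: float = 10.0
    channels: dict = field(
        default_factory=lambda: {"fluor": (100.0, 0.0, 5.0)}
    )
    foci_death_or: float = 5.0
    foci_prevalence: float = 0.5
    death_base_prob: float = 0.2
    window_min: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.lifespan_sd < 0 or self.young_cv < 0:
            raise ValueError("spreads must be >= 0")
        if self.foci_death_or <= 0:
            raise ValueError("odds ratio must be > 0")
        for name, (_, _, sd) in self.channels.items():
            if sd < 0:
                raise ValueError(f"channel {name!r}: noise SD must be >= 0")


def gen_cohort_traces(
    spec: CohortSpec,
) -> tuple[list[LineageTrace], pd.DataFrame]:
    """Generate a synthetic cohort and its ground-truth table.

    Returns traces in the same shape the simulation engine produces
    (sampled observables + event log) and a per-cell table with the planted
    lifespan, SEP generation, foci-onset indicator and death-within-window
    outcome realizing the specified odds ratio.
    """
    rng = np.random.default_rng(spec.seed)
    beta0 = math.log(spec.death_base_prob / (1.0 - spec.death_base_prob))
    beta1 = math.log(spec.foci_death_or)
    traces: list[LineageTrace] = []
    rows = []
    for i in range(spec.n):
        lifespan = max(1, int(round(rng.normal(
            spec.lifespan_mean, spec.lifespan_sd))))
        sigma = math.sqrt(math.log(1.0 + spec.young_cv**2)) \
            if spec.young_cv > 0 else 0.0
        durations = spec.young_mean_min * np.exp(
            rng.normal(0.0, sigma, size=lifespan)
        ) if sigma > 0 else np.full(lifespan, spec.young_mean_min)
        sep_gen = max(1, lifespan - spec.sep_offset + 1)
        durations[sep_gen - 1:] *= spec.post_sep_multiplier
        bud_times = np.concatenate([[0.0], np.cumsum(durations)])[:-1]
        death_time = bud_times[-1] + durations[-1]
        # foci-onset indicator coupled to death-within-window with the
        # planted odds ratio (the reading is taken one window before death
        # or one window earlier, depending on the planted outcome)
        x = int(rng.random() < spec.foci_prevalence)
        p_death = 1.0 / (1.0 + math.exp(-(beta0 + beta1 * x)))
        y = int(rng.random() < p_death)
        reading = death_time - (0.5 if y else 1.5) * spec.window_min
        reading = max(reading, 0.0)
        onset = reading - spec.window_min / 2 if x else math.nan
        grid = np.arange(0.0, death_time + spec.sampling_interval / 2,
                         spec.sampling_interval)
        df = pd.DataFrame({"time_min": grid})
        df["phase"] = "G1"
        gen_idx = np.searchsorted(bud_times, grid, side="right")
        df["generation"] = gen_idx - 1
        df["volume_fL"] = 30.0
        for name, (base, trend, sd) in spec.channels.items():
            noise = rng.normal(0.0, sd, size=len(grid)) if sd > 0 else 0.0
            df[name] = base + trend * grid + noise
        events = [(float(t), "budding") for t in bud_times]
        events.append((float(death_time), "arrest"))
        traces.append(LineageTrace(
            samples=df, events=events, lifespan=lifespan, censored=False,
            arrest_phase="G1", seed=spec.seed + i,
        ))
        rows.append({
            "cell": i,
            "lifespan": lifespan,
            "sep_generation": sep_gen,
            "death_min": death_time,
            "reading_min": reading,
            "foci_onset_min": onset,
            "foci_at_reading": x,
            "death_within_window": y,
        })
    return traces, pd.DataFrame(rows)


def gen_cell_image(
    shape: tuple[int, int] = (64, 64),
    mask: np.ndarray | None = None,
    nucleus: tuple[tuple[float, float], float] | None = None,
    foci: list[tuple[tuple[float, float], float, float]] = (),
    background: float = 100.0,
    noise_sd: float = 0.0,
    pixel_size: float = 0.1,
    nucleus_rel_intensity: float = 2.0,
    seed: int = 0,
) -> tuple[CellImage, dict]:
    """Synthesize a single-cell image with planted structures.

    ``nucleus`` is ``((row, col), radius_px)``; each focus is
    ``((row, col), diameter_um, rel_intensity)`` where the intensity is
    relative to the local background.  Planted foci must not overlap.
    Returns the image and a ground-truth dict with planted centroids/areas.
    """
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    if mask is None:
        cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
        r = min(shape) * 0.42
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
    img = np.full(shape, background, dtype=float)
    img[~mask] = 0.0
    truth: dict = {"foci": [], "nucleus": None}
    if nucleus is not None:
        (ny, nx), nrad = nucleus
        ndisc = (rr - ny) ** 2 + (cc - nx) ** 2 <= nrad**2
        img[ndisc & mask] = background * nucleus_rel_intensity
        truth["nucleus"] = {"center": (ny, nx), "radius_px": nrad}
    placed = []
    for (fy, fx), diam_um, rel in foci:
        frad_px = diam_um / 2.0 / pixel_size
        for (py, px, prad) in placed:
            if math.hypot(fy - py, fx - px) <= frad_px + prad:
                raise ValueError("planted foci overlap")
        disc = (rr - fy) ** 2 + (cc - fx) ** 2 <= frad_px**2
        if not np.all(mask[disc]):
            raise ValueError("planted focus extends outside the cell mask")
        img[disc] = background * (1.0 + rel)
        placed.append((fy, fx, frad_px))
        truth["foci"].append({
            "center": (fy, fx),
            "diameter_um": diam_um,
            "area_um2": math.pi * (diam_um / 2.0) ** 2,
            "rel_intensity": rel,
        })
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
        img[~mask] = 0.0
    return CellImage(intensity=img, cell_mask=mask,
                     pixel_size=pixel_size), truth


def gen_flip_trace(
    half_life_s: float,
    n_points: int = 60,
    dt_s: float = 0.5,
    noise_sd: float = 0.0,
    radius_um: float = 1.0,
    seed: int = 0,
) -> FlipTrace:
    """Synthesize a normalized FLIP decay trace with known half-life."""
    if half_life_s <= 0:
        raise ValueError("half_life must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt_s
    lam = math.log(2.0) / half_life_s
    f = np.exp(-lam * t)
    if noise_sd > 0:
        f = f * (1.0 + rng.normal(0.0, noise_sd, size=n_points))
    f = np.clip(f, 0.0, None)
    f[0] = 1.0
    return FlipTrace(time_s=t, signal=f, radius_um=radius_um)
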