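"""Synthetic inputs for the aggregation-quantification pipeline.

The real measurements this package analyses — dual-fluorescence micrographs
and large-particle flow-cytometry event streams of *Streptomyces* cultures —
come from instruments; this module generates statistically faithful stand-ins
with known ground truth:

* :func:`simulate_germling_aggregation` — an agent-based coalescence model of
  germling aggregation in a shaken liquid culture.  Spores inoculated in two
  colors (eGFP / mCherry reporters) germinate around 4 h; only germinated
  particles can stick together, and aggregation shuts off after ~10 h,
  reflecting the time-restricted window observed for this system.  Merging is
  volume-additive in diameter, so founder identity and total biovolume are
  conserved.
* :func:`sample_mixture` — sizes drawn from a two-component normal mixture,
  the generative twin of the model fitted by :mod:`pelletmix.size_mixture`.
* :func:`particles_to_events` — COPAS-like events (extinction, green, red)
  with configurable fluorescence bleed-through and injected debris.
* :func:`render_channels` — two-channel fluorescence images of particles as
  Gaussian blobs, with bleed-through and noise, for the imaging pipeline.

All randomness flows from an explicit per-call seed; no global state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._errors import EmptyInputError, ParameterError, PlacementError
from .size_mixture import SizeSample

__all__ = [
    "SimParams",
    "SimParticle",
    "MixtureGenParams",
    "ImageSpec",
    "sample_mixture",
    "simulate_germling_aggregation",
    "particles_to_sizes",
    "particles_to_events",
    "render_channels",
    "write_particle_table",
    "read_particle_table",
    "write_event_table",
    "read_event_table",
    "write_channel_tiffs",
    "read_channel_tiffs",
    "write_manifest",
]

#: Extinction value below which a flow event counts as debris.
DEBRIS_EXTINCTION = 25.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class SimParams:
    """Knobs of the germling-aggregation simulator.

    Defaults encode the study conditions for the wild-type-like culture:
    germination centred at 4 h, aggregation window closing at 10 h, a
    size-independent encounter kernel, and adhesion probability 1 (the
    glycan-synthase genotype; mutants lower ``adhesion``).
    """

    n_spores: int = 1000
    frac_green: float = 0.5  # remainder of the inoculum is red
    dt: float = 0.1  # hours per step
    t_end: float = 24.0  # hours
    germ_mean: float = 4.0  # germination-time mean (h)
    germ_sd: float = 1.0  # germination-time sd (h)
    growth_rate: float = 2.0  # um/h added to diameter after germination
    collision_rate: float = 1.0  # expected pairwise encounters per particle per hour
    adhesion: float = 1.0  # probability an eligible encounter merges the pair
    aggregation_t_max: float = 11.5  # eligibility window end (h)
    spore_diameter: float = 1.0  # um, ungerminated spore
    max_merge_diameter: float | None = None  # optional size-cap eligibility variant
    size_proportional_kernel: bool = False  # encounters weighted by diameter
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_spores >= 1, "n_spores: must be >= 1")
        _require(0.0 <= self.frac_green <= 1.0, "frac_green: must lie in [0, 1]")
        _require(self.dt > 0, "dt: must be > 0")
        _require(self.t_end >= 0, "t_end: must be >= 0")
        _require(self.germ_sd >= 0, "germ_sd: must be >= 0")
        _require(self.germ_mean > 0, "germ_mean: must be > 0")
        _require(self.growth_rate >= 0, "growth_rate: must be >= 0")
        _require(self.collision_rate >= 0, "collision_rate: must be >= 0")
        _require(0.0 <= self.adhesion <= 1.0, "adhesion: must lie in [0, 1]")
        _require(self.aggregation_t_max >= 0, "aggregation_t_max: must be >= 0")
        _require(self.spore_diameter > 0, "spore_diameter: must be > 0")
        if self.max_merge_diameter is not None:
            _require(self.max_merge_diameter > 0, "max_merge_diameter: must be > 0")


@dataclass
class SimParticle:
    """A (possibly multi-founder) mycelial particle.

    ``founders_green``/``founders_red`` count the spores of each color that
    coalesced into this particle; ``germ_time`` is the earliest germination
    time among them.
    """

    founders_green: int
    founders_red: int
    diameter: float
    germinated: bool
    germ_time: float

    def __post_init__(self) -> None:
        _require(self.founders_green >= 0 and self.founders_red >= 0,
                 "founder counts must be non-negative")
        _require(self.founders_green + self.founders_red >= 1,
                 "a particle needs at least one founder")
        _require(self.diameter > 0, "diameter: must be > 0")

    @property
    def n_founders(self) -> int:
        return self.founders_green + self.founders_red

    @property
    def is_dual(self) -> bool:
        return self.founders_green > 0 and self.founders_red > 0


@dataclass
class MixtureGenParams:
    """Parameters of the generative two-component normal size mixture."""

    p: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0.0 < self.p < 1.0, "p: must lie strictly inside (0, 1)")
        _require(self.sigma1 > 0, "sigma1: must be > 0")
        _require(self.sigma2 > 0, "sigma2: must be > 0")
        _require(self.mu1 <= self.mu2, "mu1: must not exceed mu2 (component 1 is small particles)")
        _require(self.n >= 1, "n: must be >= 1")


@dataclass
class ImageSpec:
    """Rendering / acquisition parameters for synthetic two-channel data.

    The bleed-through defaults (4% of red into green, 5% of green into red)
    mirror the crosstalk the flow-gating compensation removes.
    """

    width: int = 512
    height: int = 512
    blob_sigma: float = 4.0
    background: float = 100.0
    noise_sd: float = 0.0
    bleed_red_into_green: float = 0.04
    bleed_green_into_red: float = 0.05

    def __post_init__(self) -> None:
        _require(self.width >= 32 and self.height >= 32, "width/height: must be >= 32 pixels")
        _require(self.blob_sigma > 0, "blob_sigma: must be > 0")
        _require(self.background >= 0, "background: must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd: must be >= 0")
        _require(0.0 <= self.bleed_red_into_green < 1.0, "bleed_red_into_green: must lie in [0, 1)")
        _require(0.0 <= self.bleed_green_into_red < 1.0, "bleed_green_into_red: must lie in [0, 1)")


def sample_mixture(gen: MixtureGenParams) -> SizeSample:
    """Draw ``gen.n`` sizes from the two-component normal mixture.

    Each draw comes from component 1 with probability ``p``, else component 2;
    non-positive draws are redrawn, since sizes are positive.  Reproducible
    given ``gen.seed``.
    """
    rng = np.random.default_rng(gen.seed)
    comp1 = rng.random(gen.n) < gen.p
    mu = np.where(comp1, gen.mu1, gen.mu2)
    sd = np.where(comp1, gen.sigma1, gen.sigma2)
    x = rng.normal(mu, sd)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(mu[bad], sd[bad])
        bad = x <= 0
    return SizeSample(values=x, normalized=False)


def _run_steps(fg, fr, diam, germ_time, alive_idx, t_start, params, rng):
    """Advance the particle state from ``t_start`` to ``params.t_end``.

    Mutates the state arrays in place and returns the surviving indices.
    Per step: particles germinated by the step start grow linearly; inside
    the aggregation window, encounter pairs are drawn (constant per-particle
    rate, already thinned by ``adhesion``) and every eligible pair —
    both germinated, optionally both under the size cap — merges
    volume-additively, summing founder counts.  Same-step merge chains are
    resolved through a union-find redirect so an already-absorbed particle
    passes its encounters on to its absorber.
    """
    n = fg.size
    t = t_start
    while t < params.t_end - 1e-12:
        step = min(params.dt, params.t_end - t)
        # growth of particles germinated by the start of the step
        grown = alive_idx[germ_time[alive_idx] <= t]
        diam[grown] += params.growth_rate * step

        if t <= params.aggregation_t_max and params.adhesion > 0 and alive_idx.size >= 2:
            n_alive = alive_idx.size
            lam = 0.5 * params.collision_rate * n_alive * step * params.adhesion
            n_att = rng.poisson(lam)
            if n_att:
                if params.size_proportional_kernel:
                    w = diam[alive_idx]
                    w = w / w.sum()
                    a = rng.choice(alive_idx, size=n_att, p=w)
                    b = rng.choice(alive_idx, size=n_att, p=w)
                else:
                    a = alive_idx[rng.integers(0, n_alive, n_att)]
                    b = alive_idx[rng.integers(0, n_alive, n_att)]
                parent: dict[int, int] = {}

                def find(i: int) -> int:
                    while i in parent:
                        i = parent[i]
                    return i

                dead = []
                for ai, bi in zip(a.tolist(), b.tolist()):
                    ra, rb = find(ai), find(bi)
                    if ra == rb:
                        continue  # self-encounter after an earlier merge
                    if germ_time[ra] > t or germ_time[rb] > t:
                        continue  # only germinated particles aggregate
                    if params.max_merge_diameter is not None and (
                        diam[ra] > params.max_merge_diameter
                        or diam[rb] > params.max_merge_diameter
                    ):
                        continue
                    diam[ra] = float(np.cbrt(diam[ra] ** 3 + diam[rb] ** 3))
                    fg[ra] += fg[rb]
                    fr[ra] += fr[rb]
                    germ_time[ra] = min(germ_time[ra], germ_time[rb])
                    parent[rb] = ra
                    dead.append(rb)
                if dead:
                    keep = np.ones(n, dtype=bool)
                    keep[dead] = False
                    alive_idx = alive_idx[keep[alive_idx]]
        t += step
    return alive_idx


def _to_particles(fg, fr, diam, germ_time, alive_idx, t_end) -> list[SimParticle]:
    return [
        SimParticle(
            founders_green=int(fg[i]),
            founders_red=int(fr[i]),
            diameter=float(diam[i]),
            germinated=bool(germ_time[i] <= t_end),
            germ_time=float(germ_time[i]),
        )
        for i in alive_idx
    ]


def simulate_germling_aggregation(params: SimParams) -> list[SimParticle]:
    """Simulate germination, growth and germling coalescence; return the
    particle list at ``t_end``.

    Mechanics per time step of ``dt`` hours:

    * a spore germinates at a time drawn from ``Normal(germ_mean, germ_sd)``
      truncated at zero; after germination its diameter grows linearly at
      ``growth_rate``;
    * encounters between particles occur as well-mixed random pairs at a
      total rate of ``collision_rate * n_alive / 2`` per hour (a constant
      per-particle encounter rate; optionally diameter-weighted), and an
      encounter merges the pair with probability ``adhesion`` — but only if
      both partners are germinated and the current time is still inside the
      aggregation window (``t <= aggregation_t_max``);
    * merging sums founder counts and combines diameters volume-additively,
      ``d = (d1**3 + d2**3)**(1/3)``.

    Founder counts and (at zero growth) total biovolume are conserved.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_spores

    green = rng.random(n) < params.frac_green
    if params.germ_sd == 0:
        germ_time = np.full(n, params.germ_mean)
    else:
        germ_time = rng.normal(params.germ_mean, params.germ_sd, n)
        bad = germ_time < 0
        while bad.any():  # truncation at zero by redrawing
            germ_time[bad] = rng.normal(params.germ_mean, params.germ_sd, bad.sum())
            bad = germ_time < 0

    fg = green.astype(np.int64)
    fr = (~green).astype(np.int64)
    diam = np.full(n, params.spore_diameter, dtype=float)
    alive_idx = _run_steps(fg, fr, diam, germ_time, np.arange(n), 0.0, params, rng)
    return _to_particles(fg, fr, diam, germ_time, alive_idx, params.t_end)


def resume_aggregation(
    particles: list[SimParticle], params: SimParams, t_start: float, seed: int
) -> list[SimParticle]:
    """Continue growth and aggregation of an existing particle pool.

    Used by the mixing time course: two separately grown cultures are pooled
    at ``t_start`` and the co-culture continues to ``params.t_end`` under
    the same stepping rules as :func:`simulate_germling_aggregation`.
    """
    if not particles:
        raise EmptyInputError("no particles to resume from")
    _require(0 <= t_start <= params.t_end, "t_start: must lie within [0, t_end]")
    rng = np.random.default_rng(seed)
    fg = np.array([p.founders_green for p in particles], dtype=np.int64)
    fr = np.array([p.founders_red for p in particles], dtype=np.int64)
    diam = np.array([p.diameter for p in particles], dtype=float)
    germ_time = np.array([p.germ_time for p in particles], dtype=float)
    alive_idx = _run_steps(fg, fr, diam, germ_time, np.arange(fg.size), t_start, params, rng)
    return _to_particles(fg, fr, diam, germ_time, alive_idx, params.t_end)


def particles_to_sizes(particles: list[SimParticle]) -> SizeSample:
    """Diameters of the particles, in input order (raw, micrometres)."""
    if not particles:
        raise EmptyInputError("no particles to measure")
    return SizeSample(values=np.array([p.diameter for p in particles]), normalized=False)


def particles_to_events(
    particles: list[SimParticle],
    gain_ext: float = 1.0,
    gain_fluor: float = 100.0,
    spec: ImageSpec | None = None,
    n_debris: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn particles into COPAS-like flow events.

    Each particle yields one event: ``extinction = gain_ext * diameter``
    plus Gaussian noise; true green/red intensities are proportional to the
    founder counts (``gain_fluor`` per founder); observed intensities mix in
    the bleed-through fractions of ``spec``.  ``n_debris`` low-extinction
    events (extinction < 25, negligible fluorescence) are appended to mimic
    hyphal fragments.
    """
    if not particles:
        raise EmptyInputError("no particles to convert to events")
    _require(gain_ext > 0, "gain_ext: must be > 0")
    _require(gain_fluor > 0, "gain_fluor: must be > 0")
    _require(n_debris >= 0, "n_debris: must be >= 0")
    spec = spec or ImageSpec()
    rng = np.random.default_rng(seed)

    d = np.array([p.diameter for p in particles])
    tg = gain_fluor * np.array([p.founders_green for p in particles], dtype=float)
    tr = gain_fluor * np.array([p.founders_red for p in particles], dtype=float)
    obs_g = tg + spec.bleed_red_into_green * tr
    obs_r = tr + spec.bleed_green_into_red * tg
    ext = gain_ext * d
    if spec.noise_sd > 0:
        ext = ext + rng.normal(0, spec.noise_sd, d.size)
        obs_g = obs_g + rng.normal(0, spec.noise_sd, d.size)
        obs_r = obs_r + rng.normal(0, spec.noise_sd, d.size)
    ext = np.clip(ext, 0, None)
    obs_g = np.clip(obs_g, 0, None)
    obs_r = np.clip(obs_r, 0, None)

    if n_debris:
        deb_ext = rng.uniform(0.0, DEBRIS_EXTINCTION * 0.98, n_debris)
        deb_f = np.abs(rng.normal(0, max(spec.noise_sd, 1e-3), (2, n_debris)))
        ext = np.concatenate([ext, deb_ext])
        obs_g = np.concatenate([obs_g, deb_f[0]])
        obs_r = np.concatenate([obs_r, deb_f[1]])

    return pd.DataFrame({"extinction": ext, "green": obs_g, "red": obs_r})


def _place_centers(n: int, spec: ImageSpec, rng, min_sep: float, max_tries: int):
    # margin matches the integer half-width of the rendered kernel patch
    margin = float(np.ceil(4 * spec.blob_sigma)) + 1.0
    lo_x, hi_x = margin, spec.width - margin
    lo_y, hi_y = margin, spec.height - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PlacementError("canvas too small for the blob size; use a larger canvas")
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(max_tries):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
                centers.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place {n} non-overlapping particles; use a larger canvas"
            )
    return centers


#: Peak blob amplitude (a.u.) for a pure-color particle.
RENDER_PEAK = 3000.0


def render_channels(
    particles: list[SimParticle],
    layout_seed: int,
    spec: ImageSpec,
    return_centers: bool = False,
):
    """Render particles as Gaussian blobs into a (green, red) image pair.

    Particles are placed at non-overlapping random centers (rejection
    sampling; raises :class:`PlacementError` if the canvas is too crowded).
    Each blob's true green/red amplitudes are split according to its founder
    color composition; channel bleed-through is mixed in per ``spec``, then
    background and Gaussian noise are added.  Returns float images (clipped
    at zero) sharing ``spec``'s dimensions.
    """
    rng = np.random.default_rng(layout_seed)
    h, w = spec.height, spec.width
    true_g = np.zeros((h, w))
    true_r = np.zeros((h, w))
    centers = []
    if particles:
        centers = _place_centers(
            len(particles), spec, rng, min_sep=6.0 * spec.blob_sigma, max_tries=2000
        )
        half = int(np.ceil(4 * spec.blob_sigma))
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        kernel = np.exp(-(xx**2 + yy**2) / (2 * spec.blob_sigma**2))
        for part, (cx, cy) in zip(particles, centers):
            gx, gy = int(round(cx)), int(round(cy))
            frac_g = part.founders_green / part.n_founders
            sl_y = slice(gy - half, gy + half + 1)
            sl_x = slice(gx - half, gx + half + 1)
            true_g[sl_y, sl_x] += RENDER_PEAK * frac_g * kernel
            true_r[sl_y, sl_x] += RENDER_PEAK * (1.0 - frac_g) * kernel

    obs_g = true_g + spec.bleed_red_into_green * true_r + spec.background
    obs_r = true_r + spec.bleed_green_into_red * true_g + spec.background
    if spec.noise_sd > 0:
        obs_g = obs_g + rng.normal(0, spec.noise_sd, (h, w))
        obs_r = obs_r + rng.normal(0, spec.noise_sd, (h, w))
    obs_g = np.clip(obs_g, 0, None)
    obs_r = np.clip(obs_r, 0, None)
    if return_centers:
        return obs_g, obs_r, centers
    return obs_g, obs_r


# ---------------------------------------------------------------------------
# plain-text / TIFF interchange


def write_particle_table(particles: list[SimParticle], path) -> None:
    pd.DataFrame(
        {
            "founders_green": [p.founders_green for p in particles],
            "founders_red": [p.founders_red for p in particles],
            "diameter_um": [p.diameter for p in particles],
            "germ_time_h": [p.germ_time for p in particles],
        }
    ).to_csv(path, index=False)


def read_particle_table(path) -> list[SimParticle]:
    df = pd.read_csv(path)
    return [
        SimParticle(
            founders_green=int(r.founders_green),
            founders_red=int(r.founders_red),
            diameter=float(r.diameter_um),
            germinated=True,
            germ_time=float(r.germ_time_h),
        )
        for r in df.itertuples()
    ]


def write_event_table(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"extinction", "green", "red"} - set(df.columns)
    if missing:
        raise ParameterError(f"event table is missing columns: {sorted(missing)}")
    return df


def write_channel_tiffs(green: np.ndarray, red: np.ndarray, green_path, red_path) -> None:
    """Write a channel pair as 16-bit TIFFs (values clipped to the dtype)."""
    for img, path in ((green, green_path), (red, red_path)):
        tifffile.imwrite(path, np.clip(img, 0, 65535).astype(np.uint16))


def read_channel_tiffs(green_path, red_path) -> tuple[np.ndarray, np.ndarray]:
    return tifffile.imread(green_path), tifffile.imread(red_path)


def write_manifest(params, path) -> None:
    """Record every generation parameter (dataclass or dict) as JSON."""
    if hasattr(params, "__dataclass_fields__"):
        params = asdict(params)
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
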