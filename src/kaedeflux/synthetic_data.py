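"""Ground-truthed synthetic photoconversion timelapse data.

The generator emulates the assay this package quantifies: an axon in which
all Kaede has just been photoconverted (red everywhere, green almost zero)
is imaged as a two-channel z-stack every 10 minutes, 10 times.  Green Kaede
then reappears from two possible sources:

* somatic influx at the proximal end of the simulated segment (both
  conditions), and
* local synthesis confined to the growth-cone tip region — present only in
  the +UTR condition (``k_local > 0``).

Kinetics are a 1-D reaction-advection-diffusion equation on the axon's
arc length s (µm), tip at s = L(t):

    ∂G/∂t = D ∂²G/∂s² − v ∂G/∂s + k_local·1[tip region],

with influx J_soma at s = 0 and a zero-flux (closed) tip.  Converted (red)
Kaede is modelled as a stable pool at transport equilibrium: it evolves by
diffusion and optional photobleaching only, so R(s, t) is non-increasing in
time everywhere.  The solver is an explicit conservative finite-volume
scheme with upwinded advection; internal substeps enforce
D·Δt/Δs² ≤ 0.25 and v·Δt/Δs ≤ 0.5.

Rendering paints the 1-D concentrations onto a curved 2-D axon (tube of the
axon radius plus a disk of the growth-cone radius at the advancing tip),
spreads the signal over a thin set of z-slices, blurs with a Gaussian PSF,
applies photon gain, Poisson shot noise, Gaussian read noise and a constant
background, and quantises to the configured bit depth.  The tip advances
each frame by extending the arc-length domain, and a tip-anchored retrograde
trace is emitted per timepoint — the ground truth every pipeline stage can
be checked against.

Defaults are illustrative, chosen to emulate the study's acquisition (10
frames at 10-minute intervals, 32/150 µm pixels, +UTR n = 10 vs −UTR n = 6)
with a growth-cone green/red ratio that rises visibly above the proximal
axon by 90 minutes when local synthesis is on; in vivo values of D, v,
J_soma and k_local are unknown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from math import ceil, comb
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .image_io import (
    DEFAULT_FRAME_INTERVAL_MIN,
    DEFAULT_PIXEL_SIZE_UM,
    TimelapseStack,
    TracePath,
    write_hyperstack,
    write_trace_csv,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_kinetics",
    "render_frames",
    "simulate_axon",
    "generate_cohort",
    "generate_ao_volume",
]


@dataclass
class SimulationConfig:
    """All knobs of the kinetics + imaging simulator (units in field names/docs)."""

    # --- geometry ---
    axon_length_um: float = 42.0          # initial arc length of the simulated segment
    axon_radius_um: float = 0.5
    growth_cone_radius_um: float = 1.5
    tip_advance_speed_um_min: float = 0.12  # "grew noticeably" over 90 min (~11 µm)
    path_amplitude_um: float = 2.0        # gentle sine bend of the axon path
    path_wavelength_um: float = 40.0
    # --- kinetics ---
    diffusion_um2_min: float = 1.0        # D, slow effective diffusion of a tetramer
    transport_um_min: float = 0.05        # v, net anterograde drift of new protein
    soma_influx: float = 0.02             # J_soma, conc·µm/min at the proximal end
    k_local: float = 0.01                 # conc/min in the tip region (+UTR only)
    tip_region_um: float = 2.0            # growth-cone synthesis zone at the tip
    bleach_per_min: float = 0.0           # red photobleaching (red Kaede is stable)
    residual_green_fraction: float = 0.05 # green left after photoconversion
    initial_red: float = 1.0              # uniform post-conversion red concentration
    maturation_min: float = 0.0           # optional first-order green maturation lag
    ds_um: float = 0.25                   # arc-length grid spacing
    # --- imaging ---
    psf_sigma_um: float = 0.4
    background: float = 10.0              # counts
    gain: float = 300.0                   # counts per concentration unit per pixel
    read_noise_sd: float = 3.0            # counts
    shot_noise: bool = True
    n_z: int = 5
    image_shape: tuple = (96, 320)        # (Y, X) pixels
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_timepoints: int = 10
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    bit_depth: int = 16
    rng_seed: int = 0
    max_substeps_per_frame: int = 2_000_000

    def __post_init__(self) -> None:
        for name in (
            "diffusion_um2_min", "transport_um_min", "soma_influx", "k_local",
            "bleach_per_min", "tip_advance_speed_um_min", "maturation_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.residual_green_fraction <= 1.0:
            raise ValueError("residual_green_fraction must be in [0, 1]")
        if self.ds_um <= 0 or self.axon_length_um <= 0:
            raise ValueError("ds_um and axon_length_um must be positive")
        if self.n_timepoints < 1 or self.n_z < 1:
            raise ValueError("n_timepoints and n_z must be >= 1")


@dataclass
class GroundTruth:
    """Simulated concentration fields on the arc-length grid, per timepoint.

    ``green[t]`` / ``red[t]`` are cell-centred concentrations at arc positions
    ``s[t]`` (µm from the proximal end; the domain grows as the tip advances).
    """

    s: list                 # list of 1-D arrays, µm (cell centres)
    green: list             # list of 1-D arrays, concentration
    red: list               # list of 1-D arrays, concentration
    times_min: np.ndarray
    condition: str
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n_timepoints(self) -> int:
        return len(self.times_min)

    def tip_length_um(self, t: int) -> float:
        """Arc length of the domain (position of the tip) at frame t."""
        return float(self.s[t][-1] + self.config.ds_um / 2.0)

    def total_mass(self, which: str, t: int) -> float:
        """∫ c ds at frame t (rectangle rule, exact for the finite-volume scheme)."""
        c = {"green": self.green, "red": self.red}[which][t]
        return float(c.sum() * self.config.ds_um)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _stable_dt(cfg: SimulationConfig) -> tuple[float, int]:
    """Internal substep satisfying diffusion (<= 0.25) and advection CFL (<= 0.5)."""
    ds = cfg.ds_um
    dt = cfg.frame_interval_min
    if cfg.diffusion_um2_min > 0:
        dt = min(dt, 0.25 * ds * ds / cfg.diffusion_um2_min)
    if cfg.transport_um_min > 0:
        dt = min(dt, 0.5 * ds / cfg.transport_um_min)
    n_sub = ceil(cfg.frame_interval_min / dt)
    if n_sub > cfg.max_substeps_per_frame:
        raise ValueError(
            f"stability requires {n_sub} substeps per frame "
            f"(> max_substeps_per_frame={cfg.max_substeps_per_frame}); "
            "increase ds_um or the substep cap"
        )
    dt = cfg.frame_interval_min / n_sub
    assert cfg.diffusion_um2_min * dt / (ds * ds) <= 0.5 + 1e-12
    return dt, n_sub


def _advance(
    c: np.ndarray,
    dt: float,
    ds: float,
    D: float,
    v: float,
    influx: float,
    source: np.ndarray | float,
    decay: float,
) -> np.ndarray:
    """One conservative finite-volume step; zero-flux tip, influx at s=0."""
    # interior face fluxes (len n-1): upwind advection + central diffusion
    flux = v * c[:-1] - D * np.diff(c) / ds
    div = np.empty_like(c)
    div[0] = (flux[0] - (-influx)) / ds          # boundary face carries −J (influx)
    div[1:-1] = np.diff(flux) / ds
    div[-1] = (0.0 - flux[-1]) / ds              # closed tip
    return c - dt * div + dt * source - dt * decay * c


def simulate_kinetics(config: SimulationConfig) -> GroundTruth:
    """Solve the green/red kinetics; deterministic (no imaging noise involved).

    Frame 0 is the post-conversion state (G = residual·R₀, R = R₀).  Between
    frames the tip advances by extending the grid; newly added cells copy the
    previous tip concentrations (the growing tip carries its material forward).
    """
    cfg = config
    ds = cfg.ds_um
    dt, n_sub = _stable_dt(cfg)
    n0 = max(2, round(cfg.axon_length_um / ds))
    R = np.full(n0, float(cfg.initial_red))
    G = cfg.residual_green_fraction * R.copy()
    M = np.zeros_like(G)  # immature green pool (used only if maturation_min > 0)
    use_maturation = cfg.maturation_min > 0
    k_mat = 1.0 / cfg.maturation_min if use_maturation else 0.0

    s_list, g_list, r_list = [], [], []
    times = np.arange(cfg.n_timepoints) * cfg.frame_interval_min

    def record():
        s_list.append((np.arange(len(G)) + 0.5) * ds)
        g_list.append(G.copy())
        r_list.append(R.copy())

    record()
    grow_cells = cfg.tip_advance_speed_um_min * cfg.frame_interval_min / ds
    grow_acc = 0.0
    for _ in range(cfg.n_timepoints - 1):
        n_tip = max(1, round(cfg.tip_region_um / ds))
        synth = np.zeros(len(G))
        synth[-n_tip:] = cfg.k_local
        for _ in range(n_sub):
            if use_maturation:
                M = _advance(M, dt, ds, cfg.diffusion_um2_min, cfg.transport_um_min,
                             0.0, synth, k_mat)
                G = _advance(G, dt, ds, cfg.diffusion_um2_min, cfg.transport_um_min,
                             cfg.soma_influx, k_mat * M, 0.0)
            else:
                G = _advance(G, dt, ds, cfg.diffusion_um2_min, cfg.transport_um_min,
                             cfg.soma_influx, synth, 0.0)
            # red: stable pool — diffusion + bleaching only (no motor transport)
            R = _advance(R, dt, ds, cfg.diffusion_um2_min, 0.0, 0.0, 0.0,
                         cfg.bleach_per_min)
        grow_acc += grow_cells
        n_new = int(grow_acc)
        grow_acc -= n_new
        if n_new:
            G = np.concatenate([G, np.full(n_new, G[-1])])
            R = np.concatenate([R, np.full(n_new, R[-1])])
            if use_maturation:
                M = np.concatenate([M, np.full(n_new, M[-1])])
        record()

    return GroundTruth(
        s=s_list, green=g_list, red=r_list, times_min=times,
        condition="+UTR" if cfg.k_local > 0 else "-UTR", config=cfg,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

class _AxonPath:
    """Smooth planar axon path, parameterised by arc length (µm -> px coords)."""

    def __init__(self, cfg: SimulationConfig):
        ny, nx = cfg.image_shape
        margin = (cfg.growth_cone_radius_um + 3 * cfg.psf_sigma_um) / cfg.pixel_size_um
        x0_um = (margin + 2.0) * cfg.pixel_size_um
        y0_um = ny * cfg.pixel_size_um / 2.0
        max_len = (
            cfg.axon_length_um
            + cfg.tip_advance_speed_um_min * cfg.frame_interval_min * cfg.n_timepoints
            + 5.0
        )
        xs = np.linspace(0.0, max_len * 1.2, 4000)
        ys = cfg.path_amplitude_um * np.sin(2 * np.pi * xs / cfg.path_wavelength_um)
        pts_um = np.column_stack([y0_um + ys, x0_um + xs])
        seg = np.linalg.norm(np.diff(pts_um, axis=0), axis=1)
        self._s = np.concatenate([[0.0], np.cumsum(seg)])
        self._pts_um = pts_um
        self._cfg = cfg

    def points_px(self, s_um: np.ndarray) -> np.ndarray:
        """(y, x) pixel coordinates at the given arc positions (µm)."""
        y = np.interp(s_um, self._s, self._pts_um[:, 0])
        x = np.interp(s_um, self._s, self._pts_um[:, 1])
        return np.column_stack([y, x]) / self._cfg.pixel_size_um


def _paint_planes(
    cfg: SimulationConfig, path: _AxonPath, s: np.ndarray, concs: dict
) -> dict:
    """Nearest-arc-position painting of concentration fields onto the 2-D plane.

    The pixel-to-arc-position assignment is geometric, so it is computed once
    and reused for every field in ``concs`` (e.g. green and red).
    """
    ny, nx = cfg.image_shape
    px = cfg.pixel_size_um
    # dense samples along the current domain, every ~0.4 px
    step_um = 0.4 * px
    s_dense = np.arange(0.0, s[-1] + cfg.ds_um / 2.0, step_um)
    pts = path.points_px(s_dense)
    if (pts < -0.5).any() or (pts[:, 0] > ny - 0.5).any() or (pts[:, 1] > nx - 0.5).any():
        raise ValueError("axon path leaves the field of view; enlarge image_shape")
    tree = cKDTree(pts)
    yy, xx = np.mgrid[0:ny, 0:nx]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    r_axon_px = cfg.axon_radius_um / px
    dist, idx = tree.query(pix, distance_upper_bound=r_axon_px + 0.5)
    hit = np.isfinite(dist)
    # growth-cone disk at the tip, carrying the tip concentration
    tip = path.points_px(np.array([s[-1]]))[0]
    r_gc_px = cfg.growth_cone_radius_um / px
    in_disk = np.linalg.norm(pix - tip, axis=1) <= r_gc_px

    out = {}
    for role, conc in concs.items():
        c_dense = np.interp(s_dense, s, conc)
        img = np.zeros(ny * nx)
        img[hit] = c_dense[idx[hit]]
        img[in_disk] = conc[-1]
        out[role] = img.reshape(ny, nx)
    return out


def render_frames(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> tuple[TimelapseStack, list[TracePath]]:
    """Render the ground truth into a noisy two-channel timelapse + true traces.

    Traces are tip-anchored and retrograde (point 1 = tip), re-emitted per
    timepoint at 1-pixel arc-length spacing over the whole simulated segment.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.rng_seed)
    path = _AxonPath(cfg)
    ny, nx = cfg.image_shape
    sigma_px = cfg.psf_sigma_um / cfg.pixel_size_um
    # thin-z weights: symmetric binomial profile summing to 1
    w = np.array([comb(cfg.n_z - 1, k) for k in range(cfg.n_z)], dtype=float)
    w /= w.sum()
    max_val = 2 ** cfg.bit_depth - 1

    frames = np.zeros((cfg.n_timepoints, 2, cfg.n_z, ny, nx), dtype=np.uint16)
    traces: list[TracePath] = []
    for t in range(truth.n_timepoints):
        planes = _paint_planes(
            cfg, path, truth.s[t], {"green": truth.green[t], "red": truth.red[t]}
        )
        for ci, role in enumerate(("green", "red")):
            base = planes[role]
            for k in range(cfg.n_z):
                sl = gaussian_filter(base * w[k], sigma_px) * cfg.gain
                if cfg.shot_noise:
                    sl = rng.poisson(np.clip(sl, 0, None)).astype(float)
                if cfg.read_noise_sd > 0:
                    sl = sl + rng.normal(0.0, cfg.read_noise_sd, sl.shape)
                sl = sl + cfg.background
                frames[t, ci, k] = np.clip(np.rint(sl), 0, max_val).astype(np.uint16)
        # retrograde true trace: tip backwards at 1-px spacing
        tip_s = truth.s[t][-1] + cfg.ds_um / 2.0
        n_pts = int(tip_s / cfg.pixel_size_um)
        s_trace = tip_s - np.arange(n_pts) * cfg.pixel_size_um
        traces.append(TracePath(points=path.points_px(s_trace), timepoint_index=t))

    stack = TimelapseStack(
        frames=frames,
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_min=cfg.frame_interval_min,
        channel_roles={"green": 0, "red": 1},
        bit_depth=cfg.bit_depth,
    )
    return stack, traces


def simulate_axon(config: SimulationConfig):
    """Convenience: kinetics + rendering for one axon."""
    truth = simulate_kinetics(config)
    stack, traces = render_frames(truth, config)
    return truth, stack, traces


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    n_plus: int,
    n_minus: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    out_dir=None,
    k_local_cv: float = 0.3,
) -> dict:
    """Generate a +UTR / −UTR cohort with known ground truth.

    Per-axon seeds are ``seed + axon index``; +UTR axons draw their local
    synthesis rate from a lognormal around the configured ``k_local`` with
    coefficient of variation ``k_local_cv`` (biological variability), −UTR
    axons have ``k_local = 0``.  With ``out_dir`` set, stacks, traces, a
    design CSV and a truth JSON are written and the manifest holds paths;
    otherwise the objects are returned in memory.
    """
    if n_plus < 1 or n_minus < 1:
        raise ValueError("counts must be >= 1")
    base = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + k_local_cv**2))
    axons = []
    for i in range(n_plus + n_minus):
        cond = "+UTR" if i < n_plus else "-UTR"
        if cond == "+UTR":
            k = float(base.k_local * rng.lognormal(-0.5 * sigma**2, sigma))
        else:
            k = 0.0
        cfg = replace(base, k_local=k, rng_seed=seed + i)
        truth, stack, traces = simulate_axon(cfg)
        axons.append(
            {
                "axon_id": f"axon{i:02d}",
                "condition": cond,
                "seed": seed + i,
                "k_local": k,
                "truth": truth,
                "stack": stack,
                "traces": traces,
            }
        )
    manifest = {"seed": seed, "n_plus": n_plus, "n_minus": n_minus, "axons": axons}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        design_rows = []
        meta = []
        for ax in axons:
            stem = ax["axon_id"]
            stack_path = out / f"{stem}.tif"
            trace_path = out / f"{stem}_traces.csv"
            write_hyperstack(ax["stack"], stack_path)
            write_trace_csv(ax["traces"], trace_path)
            ax["stack_path"] = str(stack_path)
            ax["trace_path"] = str(trace_path)
            design_rows.append(f"{stem},{ax['condition']}")
            meta.append(
                {
                    "axon_id": stem,
                    "condition": ax["condition"],
                    "seed": ax["seed"],
                    "k_local": ax["k_local"],
                    "stack": stack_path.name,
                    "traces": trace_path.name,
                }
            )
        (out / "design.csv").write_text(
            "axon_id,condition\n" + "\n".join(design_rows) + "\n"
        )
        truth_doc = {"seed": seed, "config": asdict(base), "axons": meta}
        (out / "truth.json").write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
        manifest["design_csv"] = str(out / "design.csv")
        manifest["truth_json"] = str(out / "truth.json")
    return manifest


# ---------------------------------------------------------------------------
# apoptosis-counting fixtures
# ---------------------------------------------------------------------------

def generate_ao_volume(
    n_spots: int,
    shape: tuple = (40, 96, 96),
    spot_radius_um: float = 3.0,
    intensity: float = 100.0,
    noise_sd: float = 5.0,
    background: float = 10.0,
    voxel_size_um: float = 1.0,
    seed: int = 0,
    min_separation_factor: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy 3-D volume with ``n_spots`` planted Gaussian spots + true centroids.

    Spots are placed by rejection sampling with pairwise separation at least
    ``min_separation_factor × spot_radius_um`` and kept one radius clear of
    the borders.  A spot of radius r is rendered as a Gaussian of
    σ = r/√3 voxel-scaled, the scale at which a 3-D Laplacian-of-Gaussian
    detector reports radius r.  Returns (volume float32, centroids (n, 3) z,y,x).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    r_vox = spot_radius_um / voxel_size_um
    sep = min_separation_factor * r_vox
    centroids = []
    tries = 0
    while len(centroids) < n_spots:
        tries += 1
        if tries > 20000:
            raise ValueError("cannot place spots with the required separation")
        cand = np.array([rng.uniform(r_vox, d - 1 - r_vox) for d in shape])
        if all(np.linalg.norm(cand - c) >= sep for c in centroids):
            centroids.append(cand)
    centroids = np.array(centroids).reshape(n_spots, 3)

    vol = np.full(shape, float(background), dtype=np.float64)
    sigma = r_vox / np.sqrt(3.0)
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    for c in centroids:
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        vol += intensity * np.exp(-d2 / (2 * sigma**2))
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, shape)
    return np.clip(vol, 0, None).astype(np.float32), centroids
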