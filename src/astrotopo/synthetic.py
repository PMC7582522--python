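"""Seeded synthetic data emulating acute-slice recordings and micrographs.

Three generators stand in for the study's raw data, which were never
deposited:

* tracer-coupled astrocyte networks — anisotropic 2-D Gaussian point clouds
  around a patched cell, rendered as fluorescent spots whose brightness
  decays exponentially with distance from the patched cell;
* whole-cell voltage-step current traces — a two-resistor RC circuit
  (series resistance in series with the membrane RC), optionally with a
  Boltzmann-activated delayed-rectifier outward current for the non-passive
  astrocyte (nPA) phenotype;
* punctate immunofluorescence fields with a nucleus ROI, for mean-grey-value
  quantification.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import lfilter

from .datatypes import FluorescenceImage, NetworkPointSet, RoiPolygon
from .ephys import VoltageStepProtocol, CurrentTraceSet


# --------------------------------------------------------------------------
# tracer-coupled networks
# --------------------------------------------------------------------------

@dataclass
class SyntheticNetworkSpec:
    """Ground-truth parameters of a synthetic tracer-coupled network.

    Defaults reproduce the wild-type scale of the study system: 64 cells in
    total (63 coupled + 1 patched) whose convex hull covers ≈ 0.044 mm²,
    i.e. ≈ 1490 cells/mm².  ``alpha_true`` is the major-axis orientation in
    degrees, measured counter-clockwise from the mediolateral (+x) axis;
    90° therefore means dorsoventrally elongated (orthogonal to the
    tonotopic axis), the predominant wild-type topography.

    ``min_spacing`` imposes a soma-sized hard core (cell bodies cannot
    overlap); positions are resampled until they respect it.
    """

    n_cells: int = 63               # coupled cells; the patched cell is extra
    sigma_major: float = 75.0       # µm
    sigma_minor: float = 37.5       # µm
    alpha_true: float = 90.0        # deg from +x (mediolateral)
    peak_intensity: float = 900.0   # a.u. above background, at the patched cell
    decay_length: float = 200.0     # µm, exponential brightness decay
    background_level: float = 100.0  # a.u.
    noise_sd: float = 0.0           # a.u. additive Gaussian noise
    pixel_size: float = 1.0         # µm/pixel
    spot_sigma: float = 3.0         # µm, rendered soma spot width (FWHM ≈ 7 µm)
    min_spacing: float = 10.0       # µm hard-core distance between soma centres
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (self.sigma_major >= self.sigma_minor > 0):
            raise ValueError("need sigma_major >= sigma_minor > 0")
        if not self.decay_length > 0:
            raise ValueError("decay_length must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_network_points(spec: SyntheticNetworkSpec) -> NetworkPointSet:
    """Draw coupled-cell positions around a patched cell at the origin.

    Positions are sampled from a 2-D Gaussian with principal standard
    deviations ``(sigma_major, sigma_minor)`` rotated by ``alpha_true``,
    thinned to respect ``min_spacing``.  The ground-truth orientation is
    recorded in the spec itself.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a = np.deg2rad(spec.alpha_true)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

    accepted = [np.zeros(2)]  # patched cell at the origin
    max_tries = 200_000
    tries = 0
    while len(accepted) < spec.n_cells + 1:
        if tries >= max_tries:
            raise RuntimeError(
                "could not place all cells under the min_spacing constraint; "
                "reduce n_cells or min_spacing or increase the sigmas"
            )
        p = rot @ (rng.standard_normal(2) * [spec.sigma_major, spec.sigma_minor])
        tries += 1
        if spec.min_spacing > 0:
            d = np.hypot(*(np.asarray(accepted) - p).T)
            if np.min(d) < spec.min_spacing:
                continue
        accepted.append(p)

    pts = np.asarray(accepted)
    return NetworkPointSet(patched=pts[0], cells=pts[1:])


def render_spots(
    positions_um: np.ndarray,
    amplitudes: np.ndarray,
    *,
    pixel_size: float,
    spot_sigma: float,
    background: float,
    noise_sd: float = 0.0,
    margin_um: float = 30.0,
    seed: int = 0,
    bounds_um: tuple[float, float, float, float] | None = None,
) -> FluorescenceImage:
    """Render Gaussian spots of given peak amplitudes over a flat background.

    ``bounds_um`` = (xmin, xmax, ymin, ymax) fixes the field of view;
    otherwise the field covers all positions plus ``margin_um``.
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    positions = np.atleast_2d(np.asarray(positions_um, dtype=float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(positions),))
    if bounds_um is None:
        xmin, ymin = positions.min(axis=0) - margin_um
        xmax, ymax = positions.max(axis=0) + margin_um
    else:
        xmin, xmax, ymin, ymax = bounds_um
    ncols = int(np.ceil((xmax - xmin) / pixel_size)) + 1
    nrows = int(np.ceil((ymax - ymin) / pixel_size)) + 1
    x = xmin + np.arange(ncols) * pixel_size
    y = ymin + np.arange(nrows) * pixel_size
    img = np.full((nrows, ncols), float(background))
    two_s2 = 2.0 * spot_sigma**2
    # truncate each spot at 5 sigma to keep rendering linear in cell count
    half = 5.0 * spot_sigma
    for (px, py), amp in zip(positions, amplitudes):
        c0 = np.searchsorted(x, px - half)
        c1 = np.searchsorted(x, px + half, side="right")
        r0 = np.searchsorted(y, py - half)
        r1 = np.searchsorted(y, py + half, side="right")
        dx2 = (x[c0:c1] - px) ** 2
        dy2 = (y[r0:r1] - py) ** 2
        img[r0:r1, c0:c1] += amp * np.exp(-(dy2[:, None] + dx2[None, :]) / two_s2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    return FluorescenceImage(img, pixel_size=pixel_size, origin=(float(xmin), float(ymin)))


def render_network_image(
    points: NetworkPointSet, spec: SyntheticNetworkSpec
) -> FluorescenceImage:
    """Render a tracer-filled network as a fluorescence micrograph.

    Each cell (patched included) becomes a Gaussian spot whose peak above
    background is ``peak_intensity * exp(-r / decay_length)`` where ``r``
    is its distance from the patched cell — tracer brightness declines
    exponentially with distance.
    """
    spec.validate()
    all_pts = points.all_points()
    r = np.hypot(*(all_pts - points.patched).T)
    amps = spec.peak_intensity * np.exp(-r / spec.decay_length)
    return render_spots(
        all_pts,
        amps,
        pixel_size=spec.pixel_size,
        spot_sigma=spec.spot_sigma,
        background=spec.background_level,
        noise_sd=spec.noise_sd,
        seed=spec.seed + 1,  # decorrelated from the position stream
    )


# --------------------------------------------------------------------------
# voltage-step current traces
# --------------------------------------------------------------------------

@dataclass
class EphysGroundTruth:
    """True circuit parameters behind a synthetic voltage-step recording.

    The passive circuit is a series resistance ``r_series`` feeding the
    membrane (``r_membrane`` parallel to ``c_membrane``).  The default
    capacitance of 1 nF reflects the effective capacitance of a patched
    astrocyte coupled into a ~60-cell syncytium, far above single-cell
    values.  Non-passive astrocytes (``phenotype="nPA"``) add a
    delayed-rectifier K⁺ current ``g_max · a(V, t) · (V − E_K)`` with
    Boltzmann steady-state activation (``v_half``, ``slope_k``) and
    first-order kinetics (``tau_act``); E_K is fixed at −100 mV.
    """

    r_series: float = 5.0        # MΩ
    r_membrane: float = 10.0     # MΩ
    c_membrane: float = 1000.0   # pF (coupled syncytium)
    phenotype: str = "PA"        # "PA" or "nPA"
    g_max_outward: float = 0.0   # nS; 0 for PA
    v_half: float = -20.0        # mV
    slope_k: float = 10.0        # mV
    tau_act: float = 5.0         # ms
    e_k: float = -100.0          # mV

    def validate(self) -> None:
        if not (self.r_series > 0 and self.r_membrane > 0):
            raise ValueError("resistances must be positive")
        if self.c_membrane <= 0:
            raise ValueError("c_membrane must be positive")
        if self.g_max_outward < 0:
            raise ValueError("g_max_outward must be non-negative")
        if self.phenotype not in ("PA", "nPA"):
            raise ValueError("phenotype must be 'PA' or 'nPA'")

    @classmethod
    def npa(cls, g_max_outward: float = 50.0, **kw) -> "EphysGroundTruth":
        return cls(phenotype="nPA", g_max_outward=g_max_outward, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def _boltzmann(v: np.ndarray | float, v_half: float, k: float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / k))


def generate_voltage_step_traces(
    truth: EphysGroundTruth,
    protocol: VoltageStepProtocol | None = None,
    *,
    noise_sd_na: float = 0.0,
    filter_cutoff_khz: float = 2.9,
    seed: int = 0,
) -> CurrentTraceSet:
    """Simulate whole-cell currents for the full voltage-step family.

    Per step of amplitude ΔU from holding, the passive current jumps to
    ΔU/R_S, then relaxes with time constant R_S·R_M·C_M/(R_S + R_M) to the
    steady state ΔU/(R_S + R_M).  The membrane reversal is taken equal to
    the holding potential so the passive baseline current is zero.  For
    nPA truth the delayed-rectifier current is added (gating driven by the
    command potential — ideal-clamp approximation).  The trace is passed
    through a single-pole low-pass at ``filter_cutoff_khz`` to emulate the
    recording system's online filter.  Currents are in nA.
    """
    truth.validate()
    protocol = protocol or VoltageStepProtocol()
    protocol.validate()

    dt = 1.0 / protocol.sampling_rate           # ms
    n_base = int(round(protocol.baseline_ms / dt))
    n_step = int(round(protocol.duration / dt))
    # simulate on a fine grid (>= 500 kHz) so the "online" low-pass acts like
    # an analog filter applied before digitisation, then decimate
    oversample = max(1, int(np.ceil(500.0 / protocol.sampling_rate)))
    dt_f = dt / oversample
    t = np.arange((n_base + n_step) * oversample) * dt_f
    t_on = n_base * dt
    commands = protocol.command_voltages()

    rs, rm, cm = truth.r_series, truth.r_membrane, truth.c_membrane
    tau_ms = rs * rm / (rs + rm) * cm * 1e-3    # MΩ·pF = µs → ms
    # the phenotype string is a label; the current law depends only on g_max
    g = truth.g_max_outward

    traces = np.empty((len(commands), len(t)))
    a_hold = _boltzmann(protocol.holding, truth.v_half, truth.slope_k)
    i_k_hold = g * a_hold * (protocol.holding - truth.e_k) * 1e-3  # nS·mV = pA → nA
    for j, v in enumerate(commands):
        du = v - protocol.holding
        i_ss = du / (rs + rm)                   # mV/MΩ = nA
        i_pk = du / rs
        i = np.full(len(t), i_k_hold)
        step = t >= t_on
        ts = t[step] - t_on
        i[step] = i_ss + (i_pk - i_ss) * np.exp(-ts / tau_ms)
        a_inf = _boltzmann(v, truth.v_half, truth.slope_k)
        a_t = a_inf + (a_hold - a_inf) * np.exp(-ts / truth.tau_act)
        i[step] += g * a_t * (v - truth.e_k) * 1e-3
        traces[j] = i

    if noise_sd_na > 0:
        rng = np.random.default_rng(seed)
        traces = traces + rng.normal(0.0, noise_sd_na, traces.shape)

    if filter_cutoff_khz and filter_cutoff_khz > 0:
        tau_f = 1.0 / (2.0 * np.pi * filter_cutoff_khz)  # ms
        a1 = np.exp(-dt_f / tau_f)
        traces = lfilter([1.0 - a1], [1.0, -a1], traces, axis=1)

    # digitise at the protocol's sampling rate
    traces = traces[:, ::oversample]
    t_out = t[::oversample]
    return CurrentTraceSet(
        time_ms=t_out, currents_na=traces, command_voltages=commands, step_onset_ms=t_on
    )


# --------------------------------------------------------------------------
# punctate immunofluorescence fields
# --------------------------------------------------------------------------

def generate_immuno_field(
    roi: RoiPolygon,
    inside_density: float,
    outside_density: float,
    *,
    pixel_size: float = 0.5,
    punctum_sigma: float = 0.6,
    punctum_amplitude: float = 300.0,
    background_level: float = 50.0,
    noise_sd: float = 5.0,
    margin_um: float = 20.0,
    seed: int = 0,
) -> FluorescenceImage:
    """Render a punctate immunofluorescence field around a nucleus ROI.

    Punctum counts are Poisson with the stated densities (puncta/mm²)
    inside and outside the polygon; positions are uniform in each region.
    Densities of zero yield a pure background-plus-noise image.
    """
    if inside_density < 0 or outside_density < 0:
        raise ValueError("densities must be non-negative")
    poly = roi.shapely  # raises on degenerate input via RoiPolygon
    rng = np.random.default_rng(seed)

    xmin, ymin = roi.vertices.min(axis=0) - margin_um
    xmax, ymax = roi.vertices.max(axis=0) + margin_um
    field_area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
    roi_area_mm2 = poly.area / 1e6
    outside_area_mm2 = field_area_mm2 - roi_area_mm2

    from shapely.geometry import Point as _Pt

    def _sample(n: int, want_inside: bool) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        while len(out) < n:
            p = rng.uniform([xmin, ymin], [xmax, ymax])
            if poly.contains(_Pt(p)) == want_inside:
                out.append(p)
        return out

    n_in = rng.poisson(inside_density * roi_area_mm2)
    n_out = rng.poisson(outside_density * max(outside_area_mm2, 0.0))
    pts = _sample(n_in, True) + _sample(n_out, False)

    if not pts:
        ncols = int(np.ceil((xmax - xmin) / pixel_size)) + 1
        nrows = int(np.ceil((ymax - ymin) / pixel_size)) + 1
        img = np.full((nrows, ncols), float(background_level))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        return FluorescenceImage(
            np.clip(img, 0, None), pixel_size=pixel_size, origin=(float(xmin), float(ymin))
        )

    return render_spots(
        np.asarray(pts),
        punctum_amplitude,
        pixel_size=pixel_size,
        spot_sigma=punctum_sigma,
        background=background_level,
        noise_sd=noise_sd,
        seed=seed + 1,
        bounds_um=(xmin, xmax, ymin, ymax),
    )
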