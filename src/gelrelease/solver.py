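"""One-dimensional finite-volume diffusion solver for the two-layer well.

The axial domain stacks a gel slab (bottom, sealed) and a supernatant layer
(top, sealed).  The conserved field is the total protein concentration per
bulk volume; the solve itself is performed on the free aqueous concentration
``u``, which is continuous across the gel-media interface.  In gel cells the
two are linked through a capacity factor

    C_total = eps * (1 + K) * u,

where ``eps`` is the gel porosity (accessible water fraction) and
``K = f_b / (1 - f_b)`` the equilibrium bound/free ratio, so the gel acts as
a high-capacity reservoir relative to the media.  Fluxes on the gel side pass
through the water fraction only (mobility ``eps * D_water``), which for the
total concentration is exactly transport with the single retarded diffusivity
``D_gel = D_water / (1 + K)``.

Time stepping is implicit Euler by default (unconditionally stable,
mass-conservative to linear-solver roundoff); Crank-Nicolson is available for
accuracy studies.  An analytic one-face-open slab series solution is provided
as an independent verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .transport import TransportParams

__all__ = [
    "WellGeometry",
    "Grid",
    "SolverConfig",
    "FieldState",
    "SolverError",
    "build_geometry",
    "build_grid",
    "initial_state",
    "advance",
    "total_mass",
    "layer_masses",
    "analytic_slab_release",
]

# Largest bound fraction represented exactly; f_b above this (including 1.0)
# is clipped, making the gel capacity ~1e15 and the gel numerically immobile.
_MAX_BOUND_FRACTION = 1.0 - 1e-15


class SolverError(RuntimeError):
    """Numerical failure of the diffusion solve (instability or mass loss)."""


@dataclass(frozen=True)
class WellGeometry:
    """Cylindrical-well geometry; layer thicknesses derive from volume/area."""

    cross_section_area_m2: float
    gel_volume_m3: float
    media_volume_m3: float

    def __post_init__(self) -> None:
        for name in ("cross_section_area_m2", "gel_volume_m3", "media_volume_m3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def gel_thickness_m(self) -> float:
        return self.gel_volume_m3 / self.cross_section_area_m2

    @property
    def media_thickness_m(self) -> float:
        return self.media_volume_m3 / self.cross_section_area_m2

    def to_dict(self) -> dict:
        return {
            "cross_section_area_m2": self.cross_section_area_m2,
            "gel_volume_m3": self.gel_volume_m3,
            "media_volume_m3": self.media_volume_m3,
        }


def build_geometry(
    gel_volume_m3: float, media_volume_m3: float, cross_section_area_m2: float
) -> WellGeometry:
    """Construct the well geometry from the two liquid volumes and the well area."""
    return WellGeometry(
        cross_section_area_m2=cross_section_area_m2,
        gel_volume_m3=gel_volume_m3,
        media_volume_m3=media_volume_m3,
    )


@dataclass(frozen=True)
class SolverConfig:
    """Discretisation settings.

    ``media_mode`` selects whether the supernatant is resolved as a diffusive
    layer (default, matching a two-domain continuum solve) or treated as a
    single well-mixed compartment.  ``perfect_sink`` clamps the free
    concentration to zero at the gel-media interface (verification mode).
    """

    n_cells_gel: int = 60
    n_cells_media: int = 60
    dt_s: float = 60.0
    scheme: str = "implicit"  # "implicit" or "crank-nicolson"
    mass_tolerance: float = 1e-8
    media_mode: str = "diffusive"  # "diffusive" or "well-mixed"
    perfect_sink: bool = False

    def __post_init__(self) -> None:
        if self.n_cells_gel < 4 or self.n_cells_media < 4:
            raise ValueError("cell counts must be >= 4 per layer")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.scheme not in ("implicit", "crank-nicolson"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.media_mode not in ("diffusive", "well-mixed"):
            raise ValueError(f"unknown media_mode {self.media_mode!r}")

    def to_dict(self) -> dict:
        return {
            "n_cells_gel": self.n_cells_gel,
            "n_cells_media": self.n_cells_media,
            "dt_s": self.dt_s,
            "scheme": self.scheme,
            "mass_tolerance": self.mass_tolerance,
            "media_mode": self.media_mode,
            "perfect_sink": self.perfect_sink,
        }


@dataclass
class Grid:
    """Cell-centred axial grid over ``[0, L_gel + L_media]`` (gel at the bottom).

    ``capacity`` maps free aqueous concentration to total bulk concentration per
    cell (``eps * (1 + K)`` in gel, 1 in media); ``mobility`` is the flux
    coefficient for the free concentration gradient (``eps * D_water`` in gel,
    ``D_water`` in media, per unit cross-section).
    """

    x_m: np.ndarray
    dx_m: np.ndarray
    is_gel: np.ndarray
    diffusivity_m2_s: np.ndarray
    water_fraction: np.ndarray
    capacity: np.ndarray
    mobility: np.ndarray
    cross_section_area_m2: float

    @property
    def n_cells(self) -> int:
        return self.x_m.size

    def cell_volumes_m3(self) -> np.ndarray:
        return self.dx_m * self.cross_section_area_m2


def build_grid(
    params: TransportParams, geometry: WellGeometry, config: SolverConfig
) -> Grid:
    """Discretise the two-layer domain with per-layer uniform cells."""
    coeffs = params.diffusion_coefficients()
    f_b = min(params.bound_fraction, _MAX_BOUND_FRACTION)
    ratio = f_b / (1.0 - f_b)
    eps = params.porosity

    ng, nm = config.n_cells_gel, config.n_cells_media
    lg, lm = geometry.gel_thickness_m, geometry.media_thickness_m
    dxg, dxm = lg / ng, lm / nm
    x = np.concatenate(
        [dxg * (np.arange(ng) + 0.5), lg + dxm * (np.arange(nm) + 0.5)]
    )
    dx = np.concatenate([np.full(ng, dxg), np.full(nm, dxm)])
    is_gel = np.concatenate([np.ones(ng, bool), np.zeros(nm, bool)])

    d_gel_eff = coeffs.d_water / (1.0 + ratio) + f_b * params.binder_diffusivity_m2_s
    diffusivity = np.where(is_gel, d_gel_eff, coeffs.d_water)
    water_fraction = np.where(is_gel, eps, 1.0)
    capacity = np.where(is_gel, eps * (1.0 + ratio), 1.0)
    mobility = np.where(is_gel, eps * coeffs.d_water, coeffs.d_water)
    return Grid(
        x_m=x,
        dx_m=dx,
        is_gel=is_gel,
        diffusivity_m2_s=diffusivity,
        water_fraction=water_fraction,
        capacity=capacity,
        mobility=mobility,
        cross_section_area_m2=geometry.cross_section_area_m2,
    )


@dataclass
class FieldState:
    """Axial snapshot of total (free + bound) concentration per bulk volume."""

    time_s: float
    concentration_ng_m3: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.time_s, self.concentration_ng_m3.copy())


def initial_state(params: TransportParams, grid: Grid) -> FieldState:
    """Uniform premixed load in the gel, protein-free media."""
    c0 = params.initial_concentration_ng_mL * 1e6  # ng/mL -> ng/m^3
    conc = np.where(grid.is_gel, c0, 0.0)
    return FieldState(time_s=0.0, concentration_ng_m3=conc.astype(float))


def total_mass(state: FieldState, grid: Grid) -> float:
    """Total protein mass on the grid in ng."""
    return float(np.dot(state.concentration_ng_m3, grid.cell_volumes_m3()))


def layer_masses(state: FieldState, grid: Grid) -> tuple[float, float]:
    """(gel, media) protein masses in ng."""
    vols = grid.cell_volumes_m3()
    m = state.concentration_ng_m3 * vols
    return float(m[grid.is_gel].sum()), float(m[~grid.is_gel].sum())


def _face_conductances(grid: Grid, config: SolverConfig) -> np.ndarray:
    """Series-resistance conductances between adjacent cells, per unit area.

    The half-cell resistances use each cell's mobility, which makes the flux
    continuous across the gel-media interface where mobility and capacity jump.
    In well-mixed media mode the resistance inside the media is dropped so the
    supernatant behaves as a single stirred compartment.
    """
    mob = grid.mobility.copy()
    if config.media_mode == "well-mixed":
        # boost media mobility so the supernatant homogenises within one step
        # while the matrix stays well conditioned
        mob = np.where(grid.is_gel, mob, mob * 1e4)
    half = grid.dx_m / (2.0 * mob)
    return 1.0 / (half[:-1] + half[1:])


def _build_operator(grid: Grid, config: SolverConfig):
    """Assemble the diffusion operator L (per unit area) with sealed ends.

    Returns (L, sink_diag) where sink_diag holds the extra conductance of the
    perfect-sink interface condition (zero free concentration at the top gel
    face), applied to gel cells only.
    """
    n = grid.n_cells
    g = _face_conductances(grid, config)
    main = np.zeros(n)
    main[:-1] -= g
    main[1:] -= g
    lower = g.copy()
    upper = g.copy()
    sink = np.zeros(n)
    if config.perfect_sink:
        # Dirichlet u = 0 at the gel-media interface: the top gel cell couples
        # to a zero ghost through its half-cell resistance; media cells are
        # frozen at zero.
        i_top = int(np.sum(grid.is_gel)) - 1
        g_sink = grid.mobility[i_top] / (grid.dx_m[i_top] / 2.0)
        sink[i_top] = g_sink
        main[i_top] -= g_sink
        # decouple gel from media entirely
        main[i_top] += g[i_top]
        if i_top + 1 < n:
            main[i_top + 1] += g[i_top]
        lower[i_top] = 0.0
        upper[i_top] = 0.0
    return main, lower, upper, sink


class _Stepper:
    """Factorised theta-scheme stepper for a fixed (grid, config, dt)."""

    def __init__(self, grid: Grid, config: SolverConfig, dt: float):
        self.grid = grid
        self.config = config
        self.dt = dt
        self.theta = 1.0 if config.scheme == "implicit" else 0.5
        main, lower, upper, self.sink = _build_operator(grid, config)
        self.cap = grid.capacity * grid.dx_m  # per unit area
        n = grid.n_cells
        diag_idx = np.arange(n)
        rows = np.concatenate([diag_idx, diag_idx[:-1], diag_idx[1:]])
        cols = np.concatenate([diag_idx, diag_idx[1:], diag_idx[:-1]])
        th = self.theta

        def mat(scale):
            vals = np.concatenate(
                [self.cap / dt - scale * main, -scale * upper, -scale * lower]
            )
            return csc_matrix((vals, (rows, cols)), shape=(n, n))

        self.lhs = splu(mat(th))
        self.rhs_main = self.cap / dt + (1 - th) * main
        self.rhs_off = (1 - th)
        self.upper = upper
        self.lower = lower
        self.mask_frozen = (
            ~grid.is_gel if config.perfect_sink else np.zeros(n, bool)
        )

    def step(self, u: np.ndarray) -> np.ndarray:
        rhs = self.rhs_main * u
        if self.rhs_off != 0.0:
            rhs[:-1] += self.rhs_off * self.upper * u[1:]
            rhs[1:] += self.rhs_off * self.lower * u[:-1]
        u_new = self.lhs.solve(rhs)
        if self.config.perfect_sink:
            u_new[self.mask_frozen] = 0.0
        return u_new


def advance(
    state: FieldState, grid: Grid, config: SolverConfig, duration_s: float
) -> FieldState:
    """Diffuse the field for ``duration_s`` with sealed outer boundaries.

    The duration is split into whole steps of ``config.dt_s`` plus one shorter
    remainder step.  Raises :class:`SolverError` on significant negative
    concentrations (Crank-Nicolson oscillation) or, in sealed mode, on loss of
    mass beyond ``config.mass_tolerance``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    u = state.concentration_ng_m3 / grid.capacity
    mass_before = float(np.dot(grid.capacity * grid.dx_m, u))

    n_full = int(np.floor(duration_s / config.dt_s + 1e-9))
    remainder = duration_s - n_full * config.dt_s
    if remainder < 1e-9 * config.dt_s:
        remainder = 0.0

    if n_full:
        stepper = _Stepper(grid, config, config.dt_s)
        for _ in range(n_full):
            u = stepper.step(u)
    if remainder:
        u = _Stepper(grid, config, remainder).step(u)

    scale = max(np.max(np.abs(u)), 1e-300)
    if np.min(u) < -1e-8 * scale:
        raise SolverError(
            "negative concentration detected; reduce the time step or use the "
            "implicit scheme"
        )
    np.clip(u, 0.0, None, out=u)

    if not config.perfect_sink:
        mass_after = float(np.dot(grid.capacity * grid.dx_m, u))
        if mass_before > 0 and abs(mass_after - mass_before) > (
            config.mass_tolerance * mass_before
        ):
            raise SolverError(
                f"mass balance violated: relative drift "
                f"{abs(mass_after - mass_before) / mass_before:.3e}"
            )
    return FieldState(
        time_s=state.time_s + duration_s, concentration_ng_m3=u * grid.capacity
    )


def analytic_slab_release(
    diffusivity_m2_s: float, thickness_m: float, t_s: float | np.ndarray
) -> float | np.ndarray:
    """Released fraction for a uniformly loaded slab with one face open to a
    perfect sink and the other sealed.

    ``M_t / M_inf = 1 - sum_n 8 / ((2n+1)^2 pi^2) exp(-(2n+1)^2 pi^2 D t / (4 L^2))``

    Classical separation-of-variables series; used as the independent oracle
    for the finite-volume solver.
    """
    if diffusivity_m2_s < 0:
        raise ValueError("diffusivity must be >= 0")
    if thickness_m <= 0:
        raise ValueError("thickness must be > 0")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    tau = diffusivity_m2_s * t / thickness_m**2  # dimensionless time
    n = np.arange(0, 2000)
    lam = (2 * n + 1) ** 2 * np.pi**2 / 4.0
    coef = 8.0 / ((2 * n + 1) ** 2 * np.pi**2)
    series = np.sum(
        coef * np.exp(-np.outer(np.atleast_1d(tau), lam)), axis=1
    )
    out = np.clip(1.0 - series, 0.0, 1.0)
    out = np.where(np.atleast_1d(tau) == 0.0, 0.0, out)
    if np.isscalar(t_s) or np.asarray(t_s).ndim == 0:
        return float(out[0])
    return out
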