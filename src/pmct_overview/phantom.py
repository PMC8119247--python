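"""Synthetic CT phantoms with known ground truth.

Every processing stage is testable without real postmortem data: the
generator paints simple geometric bodies at realistic Hounsfield values —
background air (~ -1000 HU), a soft-tissue ellipsoid body (~ 40 HU)
enclosing gas pockets (~ -800 HU), bone-density structures (~ 1200 HU),
metal implants (> 2800 HU) — and, optionally, a hollow air-filled table
arc below the body whose cavity is watertight, i.e. not face-connected to
the corner-reachable background air.  Alongside the volume it returns
exact ground-truth masks (exterior air incl. table cavity, interior gas,
metal).

Geometry is specified in voxel coordinates; painting proceeds background
-> table -> body -> bones -> metal -> gas (later wins).  Optional
Gaussian noise is truncated at three standard deviations and the spec is
rejected if 3*sd could push any tissue class across a decision threshold,
so ground-truth masks stay exact even with noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .io_ct import CTVolume

__all__ = [
    "Sphere",
    "Cylinder",
    "Ellipsoid",
    "TableArc",
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomSpecError",
    "generate_phantom",
    "standard_fixtures",
]

# decision thresholds the noise must never let a class cross
_DECISION_THRESHOLDS_HU = (-200.0, -220.0, 2800.0)


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float
    hu: float


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned cylinder: ``axis`` in {'x','y','z'}, extent 2*half_length."""

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: str
    hu: float


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    hu: float


@dataclass(frozen=True)
class TableArc:
    """A table arc below the body, extruded along z.

    The arc is the set of in-plane points at radius ``r_inner..r_outer``
    from ``center_xy`` within ``half_angle_deg`` of the posterior (+y)
    direction.  When ``hollow`` is true, an air-filled cavity inset by
    ``shell_thickness`` voxels radially and ``cavity_angle_inset_deg``
    angularly is carved out, leaving a watertight shell.
    """

    center_xy: tuple[float, float]
    r_inner: float
    r_outer: float
    half_angle_deg: float = 35.0
    shell_hu: float = 300.0
    cavity_hu: float = -1000.0
    hollow: bool = True
    shell_thickness: float = 1.5
    cavity_angle_inset_deg: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic CT volume."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = -1000.0
    body: Ellipsoid | None = None
    bones: tuple = ()
    metal_objects: tuple[Sphere, ...] = ()
    gas_pockets: tuple[Sphere, ...] = ()
    airways: tuple[Cylinder, ...] = ()
    table: TableArc | None = None
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bones", tuple(self.bones))
        object.__setattr__(self, "metal_objects", tuple(self.metal_objects))
        object.__setattr__(self, "gas_pockets", tuple(self.gas_pockets))
        object.__setattr__(self, "airways", tuple(self.airways))


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Exact voxel masks of the painted classes (pairwise disjoint)."""

    exterior_air_mask: np.ndarray  # background air + table cavity
    interior_gas_mask: np.ndarray  # gas pockets and airway gas
    metal_mask: np.ndarray


# ---------------------------------------------------------------------------
# validation

def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise PhantomSpecError(msg)


def _sphere_in_bounds(s: Sphere, shape) -> bool:
    return all(
        s.center[a] - s.radius >= 0 and s.center[a] + s.radius <= shape[a] - 1
        for a in range(3)
    )


def _sphere_inside_ellipsoid(s: Sphere, e: Ellipsoid) -> bool:
    # conservative: center's normalized radius plus sphere radius over the
    # smallest semi-axis stays strictly below 1
    d = np.linalg.norm(
        [(s.center[a] - e.center[a]) / e.radii[a] for a in range(3)]
    )
    return d + s.radius / min(e.radii) < 1.0


def _validate(spec: PhantomSpec) -> None:
    nx, ny, nz = spec.shape
    _require(min(spec.shape) >= 2, "every dimension must be >= 2")
    _require(all(s > 0 for s in spec.spacing), "spacing must be positive")
    if spec.body is not None:
        b = spec.body
        _require(
            all(
                b.center[a] - b.radii[a] >= 0
                and b.center[a] + b.radii[a] <= spec.shape[a] - 1
                for a in range(3)
            ),
            "body ellipsoid exceeds the volume bounds",
        )
    for s in spec.metal_objects + spec.gas_pockets:
        _require(_sphere_in_bounds(s, spec.shape), f"object out of bounds: {s}")
        _require(spec.body is not None, "gas/metal objects require a body")
        _require(
            _sphere_inside_ellipsoid(s, spec.body),
            f"object not strictly inside the body: {s}",
        )
    if spec.noise_sd < 0:
        raise PhantomSpecError("noise_sd must be non-negative")
    if spec.noise_sd > 0:
        hus = [spec.background_hu]
        if spec.body:
            hus.append(spec.body.hu)
        hus += [o.hu for o in spec.bones]
        hus += [o.hu for o in spec.metal_objects]
        hus += [o.hu for o in spec.gas_pockets]
        hus += [o.hu for o in spec.airways]
        if spec.table:
            hus.append(spec.table.shell_hu)
            if spec.table.hollow:
                hus.append(spec.table.cavity_hu)
        margin = min(
            abs(hu - thr) for hu in hus for thr in _DECISION_THRESHOLDS_HU
        )
        _require(
            3.0 * spec.noise_sd < margin,
            f"3*noise_sd ({3 * spec.noise_sd}) must stay below the smallest "
            f"HU distance to a decision threshold ({margin})",
        )


# ---------------------------------------------------------------------------
# painting

def _grids(shape):
    return np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]


def _sphere_mask(s: Sphere, grids) -> np.ndarray:
    gx, gy, gz = grids
    return (
        (gx - s.center[0]) ** 2
        + (gy - s.center[1]) ** 2
        + (gz - s.center[2]) ** 2
    ) <= s.radius**2


def _cylinder_mask(c: Cylinder, grids) -> np.ndarray:
    gx, gy, gz = grids
    coords = {"x": gx, "y": gy, "z": gz}
    ax = coords[c.axis]
    axes = [a for a in "xyz" if a != c.axis]
    r2 = sum(
        (coords[a] - c.center["xyz".index(a)]) ** 2 for a in axes
    )
    along = abs(ax - c.center["xyz".index(c.axis)])
    return (r2 <= c.radius**2) & (along <= c.half_length)


def _ellipsoid_mask(e: Ellipsoid, grids) -> np.ndarray:
    gx, gy, gz = grids
    return (
        ((gx - e.center[0]) / e.radii[0]) ** 2
        + ((gy - e.center[1]) / e.radii[1]) ** 2
        + ((gz - e.center[2]) / e.radii[2]) ** 2
    ) <= 1.0


def _table_masks(t: TableArc, grids) -> tuple[np.ndarray, np.ndarray]:
    """(shell_mask, cavity_mask) of the arc; cavity empty when solid."""
    gx, gy, gz = grids
    dx = gx - t.center_xy[0]
    dy = gy - t.center_xy[1]
    rho = np.sqrt(dx**2 + dy**2)
    # angle measured from the posterior (+y) direction
    ang = np.degrees(np.abs(np.arctan2(dx, dy))) + 0.0 * gz
    body_ring = (rho >= t.r_inner) & (rho <= t.r_outer) & (ang <= t.half_angle_deg)
    if not t.hollow:
        return body_ring, np.zeros_like(body_ring)
    cav = (
        (rho >= t.r_inner + t.shell_thickness)
        & (rho <= t.r_outer - t.shell_thickness)
        & (ang <= t.half_angle_deg - t.cavity_angle_inset_deg)
    )
    return body_ring & ~cav, cav


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomGroundTruth]:
    """Paint the phantom and derive its exact ground-truth masks.

    Deterministic for a fixed spec (including ``rng_seed``); a watertight
    table cavity is verified after painting by a corner flood fill.
    """
    _validate(spec)
    shape = tuple(spec.shape)
    grids = _grids(shape)

    hu = np.full(shape, float(spec.background_hu))
    background = np.ones(shape, dtype=bool)
    cavity = np.zeros(shape, dtype=bool)
    gas = np.zeros(shape, dtype=bool)
    metal = np.zeros(shape, dtype=bool)

    def paint(mask: np.ndarray, value: float) -> None:
        hu[mask] = value
        background[mask] = False

    if spec.table is not None:
        shell, cav = _table_masks(spec.table, grids)
        paint(shell, spec.table.shell_hu)
        paint(cav, spec.table.cavity_hu)
        cavity = cav
    if spec.body is not None:
        body = _ellipsoid_mask(spec.body, grids)
        paint(body, spec.body.hu)
        cavity &= ~body
    for bone in spec.bones:
        m = (
            _sphere_mask(bone, grids)
            if isinstance(bone, Sphere)
            else _cylinder_mask(bone, grids)
        )
        paint(m, bone.hu)
    for obj in spec.metal_objects:
        m = _sphere_mask(obj, grids)
        paint(m, obj.hu)
        metal |= m
    for pocket in spec.gas_pockets:
        m = _sphere_mask(pocket, grids)
        paint(m, pocket.hu)
        gas |= m
        metal &= ~m
    for duct in spec.airways:
        m = _cylinder_mask(duct, grids)
        # the part of the channel outside the body is background air
        inside = (
            _ellipsoid_mask(spec.body, grids) if spec.body is not None else m
        )
        paint(m & inside, duct.hu)
        hu[m & ~inside] = spec.background_hu
        background[m & ~inside] = True
        gas |= m & inside
        metal &= ~m

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        noise = rng.normal(0.0, spec.noise_sd, size=shape)
        lim = 3.0 * spec.noise_sd
        hu += np.clip(noise, -lim, lim)

    if spec.table is not None and spec.table.hollow:
        _check_cavity_watertight(hu, cavity)

    truth = PhantomGroundTruth(
        exterior_air_mask=background | cavity,
        interior_gas_mask=gas,
        metal_mask=metal,
    )
    volume = CTVolume(hu, spec.spacing)
    return volume, truth


def _check_cavity_watertight(hu: np.ndarray, cavity: np.ndarray) -> None:
    """Cavity voxels must not share a face-connected air component with a corner."""
    if not cavity.any():
        raise PhantomSpecError("hollow table produced no cavity voxels")
    air = hu <= -200.0
    labels, _ = ndi.label(air, structure=ndi.generate_binary_structure(3, 1))
    corner_labels = {
        int(labels[i, j, k])
        for i in (0, -1)
        for j in (0, -1)
        for k in (0, -1)
    } - {0}
    cavity_labels = set(np.unique(labels[cavity])) - {0}
    if cavity_labels & corner_labels:
        raise PhantomSpecError(
            "table cavity is connected to the background air (shell leaks)"
        )


# ---------------------------------------------------------------------------
# standard fixtures

def standard_fixtures() -> dict[str, PhantomSpec]:
    """Named phantom specs covering every behaviour the pipeline must show.

    * ``body_only`` — soft-tissue ellipsoid with a bone rod, nothing else.
    * ``body_with_gas`` — adds a fully enclosed gas pocket (renders blue).
    * ``body_with_metal`` — adds a metal sphere (renders red).
    * ``body_with_hollow_table`` — adds a hollow, air-filled table arc
      whose cavity the corner seeds cannot reach.
    * ``open_airway`` — a gas channel connects an interior gas region to
      the background air; corner-seeded growing absorbs it, reproducing
      the known failure mode for uncompromised airways.

    All fixtures are 48 x 48 x 40 voxels at 1 mm isotropic spacing.
    """
    shape = (48, 48, 40)
    body = Ellipsoid(center=(24, 20, 20), radii=(16, 12, 18), hu=40.0)
    spine = Cylinder(center=(24, 26, 20), radius=2.5, half_length=14, axis="z", hu=1200.0)
    base = dict(shape=shape, body=body, bones=(spine,))

    gas = Sphere(center=(17, 18, 22), radius=4.0, hu=-800.0)
    metal = Sphere(center=(30, 18, 16), radius=3.0, hu=3200.0)
    table = TableArc(center_xy=(24, 10), r_inner=23.0, r_outer=28.0)
    airway = Cylinder(center=(17, 30, 22), radius=1.5, half_length=17, axis="y", hu=-800.0)

    return {
        "body_only": PhantomSpec(**base),
        "body_with_gas": PhantomSpec(**base, gas_pockets=(gas,)),
        "body_with_metal": PhantomSpec(**base, metal_objects=(metal,)),
        "body_with_hollow_table": PhantomSpec(
            **base, gas_pockets=(gas,), table=table
        ),
        "open_airway": PhantomSpec(**base, gas_pockets=(gas,), airways=(airway,)),
    }
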