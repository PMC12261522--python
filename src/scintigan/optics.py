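"""Toy Monte Carlo optical photon transport in a cuboid scintillator.

The model is a desk-scale stand-in for a full Geant4-style optical
simulation: photons are emitted isotropically at a point inside the
crystal, fly in straight lines, suffer exponential bulk attenuation,
reflect diffusely (Lambertian) off the five reflector-wrapped faces with
a scalar survival probability, and hit the exit face where an
unpolarized Fresnel coin decides between specular reflection back into
the crystal and refraction into the optical coupling medium.  Photons
that transmit through the exit face are recorded with their position,
refracted direction and (unchanged) energy — the phase space a
photodetector would see.

Coordinate frame: the origin sits at the centre of the exit
(photodetector) face; X and Y span the face, Z increases away from the
detector, so the crystal occupies ``|x| <= half_width_x``,
``|y| <= half_width_y``, ``0 <= z <= length_z`` and detected photons
have dZ < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CrystalGeometry",
    "Photon",
    "EmissionSpectrum",
    "YieldModel",
    "TraceOutcome",
    "sample_emission_spectrum",
    "isotropic_directions",
    "fresnel_reflectance",
    "refract",
    "trace_photon",
    "trace_photons",
    "simulate_point",
    "sample_events",
]

#: fixed column order of a phase-space table
PHASESPACE_COLUMNS = ("X", "Y", "dX", "dY", "dZ", "EKine", "emX", "emY", "emZ")


@dataclass(frozen=True)
class CrystalGeometry:
    """Cuboid scintillator with five diffuse-reflector faces and one exit face.

    Defaults model a 3 x 3 x 10 mm^3 BGO crystal wrapped in Teflon and
    optically coupled to the photodetector through epoxy (n = 1.56).
    """

    half_width_x: float = 1.5  # mm
    half_width_y: float = 1.5  # mm
    length_z: float = 10.0  # mm
    n_crystal: float = 2.15  # literature BGO refractive index at ~480 nm
    n_coupling: float = 1.56  # epoxy
    reflector_reflectivity: float = 0.95
    attenuation_length: float = 300.0  # mm; bulk absorption (scattering folded in)
    max_bounces: int = 1000

    def __post_init__(self) -> None:
        if not (self.half_width_x > 0 and self.half_width_y > 0 and self.length_z > 0):
            raise ValueError("crystal half-widths and length must be strictly positive")
        if not 0.0 <= self.reflector_reflectivity <= 1.0:
            raise ValueError("reflector_reflectivity must lie in [0, 1]")
        if self.n_crystal < 1.0 or self.n_coupling < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if self.attenuation_length <= 0:
            raise ValueError("attenuation_length must be positive (use np.inf for none)")
        if self.max_bounces < 1:
            raise ValueError("max_bounces must be a positive integer")

    def contains(self, point) -> bool:
        """True if *point* lies strictly inside the crystal volume."""
        x, y, z = np.asarray(point, dtype=float)
        return (
            abs(x) < self.half_width_x
            and abs(y) < self.half_width_y
            and 0.0 < z < self.length_z
        )


@dataclass
class Photon:
    """A single optical photon in flight."""

    position: np.ndarray  # mm, 3-vector
    direction: np.ndarray  # unit 3-vector
    energy: float  # eV
    bounces: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("photon direction must be a unit vector")
        if self.energy <= 0:
            raise ValueError("photon energy must be positive")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Gaussian stand-in for a scintillation emission spectrum.

    Defaults approximate the BGO emission peak (~480 nm ~ 2.58 eV).
    Sampled energies are resampled until strictly positive.
    """

    mean_energy: float = 2.58  # eV
    sd_energy: float = 0.15  # eV

    def __post_init__(self) -> None:
        if self.mean_energy <= 0:
            raise ValueError("mean_energy must be positive")
        if self.sd_energy < 0:
            raise ValueError("sd_energy must be non-negative")


@dataclass(frozen=True)
class YieldModel:
    """Number of optical photons produced per scintillation event.

    Poisson by construction; the default mean corresponds to a 420 keV
    photoelectron in BGO at roughly 2 400 detected-scale photons per
    event, so 1000 Bq over one second yields ~2.4-2.5 million photons.
    """

    mean_photons_per_event: float = 2400.0

    def __post_init__(self) -> None:
        if self.mean_photons_per_event < 0:
            raise ValueError("mean_photons_per_event must be non-negative")


class TraceOutcome:
    """Symbolic outcomes of tracing one photon."""

    EXIT = "exit"
    ABSORBED = "absorbed"
    CAPPED = "capped"


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def sample_emission_spectrum(n, spectrum, seed=None, rng=None):
    """Draw ``n`` strictly positive photon energies (eV) from *spectrum*."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed) if rng is None else rng
    if spectrum.sd_energy == 0.0:
        return np.full(n, spectrum.mean_energy, dtype=float)
    energies = rng.normal(spectrum.mean_energy, spectrum.sd_energy, size=n)
    bad = energies <= 0.0
    while np.any(bad):
        energies[bad] = rng.normal(spectrum.mean_energy, spectrum.sd_energy, size=bad.sum())
        bad = energies <= 0.0
    return energies


def isotropic_directions(n, seed=None, rng=None):
    """Draw ``n`` unit 3-vectors uniformly on the sphere."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed) if rng is None else rng
    cos_theta = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    return np.column_stack(
        (sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta)
    )


def fresnel_reflectance(cos_incidence, n_in, n_out):
    """Unpolarized Fresnel reflectance at a planar dielectric interface.

    Average of the s- and p-polarized power reflectances.  Returns
    exactly 1 beyond the critical angle when ``n_in > n_out``.
    ``cos_incidence`` may be a scalar or array in (0, 1].
    """
    cos_i = np.asarray(cos_incidence, dtype=float)
    if np.any(cos_i <= 0.0) or np.any(cos_i > 1.0):
        raise ValueError("cos_incidence must lie in (0, 1]")
    if n_in < 1.0 or n_out < 1.0:
        raise ValueError("refractive indices must be >= 1")
    sin_i2 = 1.0 - cos_i**2
    sin_t2 = (n_in / n_out) ** 2 * sin_i2
    tir = sin_t2 >= 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin_t2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
        rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
        r = 0.5 * (rs**2 + rp**2)
    r = np.where(tir, 1.0, r)
    r = np.clip(r, 0.0, 1.0)
    return float(r) if np.isscalar(cos_incidence) or r.ndim == 0 else r


class TotalInternalReflection(Exception):
    """Signal (not an error) that refraction is impossible at this angle."""


def refract(direction, normal, n_in, n_out):
    """Refract a unit *direction* through a plane with outward unit *normal*.

    ``direction`` must point into the surface (``direction . normal > 0``).
    Returns the transmitted unit vector, or raises
    :class:`TotalInternalReflection` beyond the critical angle.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    cos_i = float(d @ nrm)
    if cos_i <= 0:
        raise ValueError("direction must point into the surface (direction . normal > 0)")
    eta = n_in / n_out
    sin_t2 = eta**2 * (1.0 - cos_i**2)
    if sin_t2 >= 1.0:
        raise TotalInternalReflection
    cos_t = np.sqrt(1.0 - sin_t2)
    t = eta * d + (cos_t - eta * cos_i) * nrm
    return t / np.linalg.norm(t)


# ---------------------------------------------------------------------------
# vectorized transport kernel
# ---------------------------------------------------------------------------

_EPS_PUSH = 1e-12  # nudge off a face after reflection to avoid zero-length steps


def _lambertian(normals_axis, normals_sign, n, rng):
    """Cosine-lobe directions about the inward normal of an axis-aligned face.

    ``normals_axis`` (int array) gives the axis of the face normal,
    ``normals_sign`` the sign of the *inward* normal component.
    """
    u1 = rng.random(n)
    u2 = rng.random(n)
    sin_t = np.sqrt(u1)
    cos_t = np.sqrt(1.0 - u1)
    phi = 2.0 * np.pi * u2
    local = np.column_stack((sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t))
    out = np.empty_like(local)
    # map local z onto the inward normal; local x/y onto the other two axes
    for axis in range(3):
        sel = normals_axis == axis
        if not np.any(sel):
            continue
        other = [a for a in range(3) if a != axis]
        out[sel, axis] = local[sel, 2] * normals_sign[sel]
        out[sel, other[0]] = local[sel, 0]
        out[sel, other[1]] = local[sel, 1]
    return out


def trace_photons(positions, directions, energies, geometry, rng):
    """Trace a batch of photons to termination.  Vectorized over photons.

    Returns ``(exit_records, outcomes)`` where *exit_records* is an
    ``(m, 6)`` array of X, Y, dX, dY, dZ, EKine rows for photons that
    transmitted through the exit face and *outcomes* is a length-n array
    of :class:`TraceOutcome` strings in input order.
    """
    pos = np.array(positions, dtype=float, copy=True).reshape(-1, 3)
    dirs = np.array(directions, dtype=float, copy=True).reshape(-1, 3)
    en = np.asarray(energies, dtype=float).reshape(-1)
    n = pos.shape[0]
    if not (dirs.shape[0] == n and en.shape[0] == n):
        raise ValueError("positions, directions and energies must have equal length")
    inside = (
        (np.abs(pos[:, 0]) < geometry.half_width_x)
        & (np.abs(pos[:, 1]) < geometry.half_width_y)
        & (pos[:, 2] > 0.0)
        & (pos[:, 2] < geometry.length_z)
    )
    if not np.all(inside):
        raise ValueError("all photons must start strictly inside the crystal")

    lo = np.array([-geometry.half_width_x, -geometry.half_width_y, 0.0])
    hi = np.array([geometry.half_width_x, geometry.half_width_y, geometry.length_z])

    outcomes = np.full(n, "", dtype=object)
    exit_rows = []
    exit_idx = []

    active = np.arange(n)
    bounces = 0
    while active.size and bounces <= geometry.max_bounces:
        p = pos[active]
        d = dirs[active]

        # distance to each of the six planes along the flight direction
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lo - p) / d
            t_hi = (hi - p) / d
        t_cand = np.where(d < 0, t_lo, np.where(d > 0, t_hi, np.inf))
        axis = np.argmin(t_cand, axis=1)
        t = t_cand[np.arange(active.size), axis]

        # bulk attenuation over the flight path
        if np.isfinite(geometry.attenuation_length):
            survive = rng.random(active.size) < np.exp(-t / geometry.attenuation_length)
        else:
            survive = np.ones(active.size, dtype=bool)
        absorbed_bulk = ~survive
        outcomes[active[absorbed_bulk]] = TraceOutcome.ABSORBED

        p = p + t[:, None] * d
        hit_sign = np.sign(d[np.arange(active.size), axis])

        at_exit = (axis == 2) & (hit_sign < 0)
        reflector = ~at_exit

        # --- exit face: Fresnel coin, refract on transmission ----------
        ex = survive & at_exit
        if np.any(ex):
            cos_i = -d[ex, 2]
            r = fresnel_reflectance(cos_i, geometry.n_crystal, geometry.n_coupling)
            r = np.atleast_1d(r)
            transmit = rng.random(ex.sum()) < (1.0 - r)
            ex_idx = np.flatnonzero(ex)
            tr_idx = ex_idx[transmit]
            if tr_idx.size:
                dt = d[tr_idx]
                eta = geometry.n_crystal / geometry.n_coupling
                cos_t = np.sqrt(1.0 - eta**2 * (1.0 - dt[:, 2] ** 2))
                new_d = eta * dt.copy()
                # outward normal is (0, 0, -1); cos_i = -dz
                new_d[:, 2] = eta * dt[:, 2] - (cos_t - eta * (-dt[:, 2])) * 1.0
                new_d /= np.linalg.norm(new_d, axis=1, keepdims=True)
                rows = np.column_stack(
                    (p[tr_idx, 0], p[tr_idx, 1], new_d, en[active[tr_idx]])
                )
                exit_rows.append(rows)
                exit_idx.append(active[tr_idx])
                outcomes[active[tr_idx]] = TraceOutcome.EXIT
            # reflected photons bounce specularly in z
            rf_idx = ex_idx[~transmit]
            d[rf_idx, 2] = -d[rf_idx, 2]
            p[rf_idx, 2] = _EPS_PUSH

        # --- reflector faces: Lambertian with survival probability -----
        rw = survive & reflector
        if np.any(rw):
            keep = rng.random(rw.sum()) < geometry.reflector_reflectivity
            rw_idx = np.flatnonzero(rw)
            lost = rw_idx[~keep]
            outcomes[active[lost]] = TraceOutcome.ABSORBED
            kept = rw_idx[keep]
            if kept.size:
                ax = axis[kept]
                inward = -hit_sign[kept]
                d[kept] = _lambertian(ax, inward, kept.size, rng)
                # nudge position just inside the face
                p[kept, ax] = np.clip(
                    p[kept, ax],
                    lo[ax] + _EPS_PUSH,
                    hi[ax] - _EPS_PUSH,
                )
            rw_done = np.zeros(active.size, dtype=bool)
            rw_done[lost] = True
        else:
            rw_done = np.zeros(active.size, dtype=bool)

        pos[active] = p
        dirs[active] = d

        done = absorbed_bulk | (survive & at_exit & (outcomes[active] == TraceOutcome.EXIT)) | rw_done
        active = active[~done]
        bounces += 1

    outcomes[active] = TraceOutcome.CAPPED

    if exit_rows:
        records = np.concatenate(exit_rows, axis=0)
        order = np.argsort(np.concatenate(exit_idx), kind="stable")
        records = records[order]
    else:
        records = np.empty((0, 6), dtype=float)
    return records, outcomes


def trace_photon(photon, geometry, seed=None, rng=None):
    """Trace a single :class:`Photon`; returns ``(outcome, record_or_None)``.

    *record* is the 6-vector X, Y, dX, dY, dZ, EKine when the outcome is
    :data:`TraceOutcome.EXIT`, else ``None``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    records, outcomes = trace_photons(
        photon.position[None, :], photon.direction[None, :], [photon.energy], geometry, rng
    )
    outcome = outcomes[0]
    return outcome, (records[0] if outcome == TraceOutcome.EXIT else None)


# ---------------------------------------------------------------------------
# phase-space production
# ---------------------------------------------------------------------------


def simulate_point(point, n_photons, geometry=None, spectrum=None, seed=None, rng=None):
    """Simulate ``n_photons`` emitted at *point*; return the detected table.

    One row per photon that reaches the photodetector (detection
    efficiency is 1), with the emission coordinates attached.  The row
    count is at most ``n_photons``.
    """
    geometry = CrystalGeometry() if geometry is None else geometry
    spectrum = EmissionSpectrum() if spectrum is None else spectrum
    if n_photons < 0:
        raise ValueError("n_photons must be non-negative")
    point = np.asarray(point, dtype=float)
    if not geometry.contains(point):
        raise ValueError(f"emission point {point.tolist()} lies outside the crystal")
    rng = np.random.default_rng(seed) if rng is None else rng

    if n_photons == 0:
        return pd.DataFrame({c: np.empty(0, dtype=float) for c in PHASESPACE_COLUMNS})

    dirs = isotropic_directions(n_photons, rng=rng)
    energies = sample_emission_spectrum(n_photons, spectrum, rng=rng)
    positions = np.tile(point, (n_photons, 1))
    records, _ = trace_photons(positions, dirs, energies, geometry, rng)

    table = pd.DataFrame(records, columns=list(PHASESPACE_COLUMNS[:6]))
    table["emX"] = point[0]
    table["emY"] = point[1]
    table["emZ"] = point[2]
    return table


def sample_events(activity, duration, yield_model=None, emission_point=(0.5, 0.5, 1.0), seed=None):
    """Draw scintillation events for a source of given *activity* (Bq).

    The number of events is Poisson(activity x duration); each event
    carries an integer photon count ``n_op`` drawn from *yield_model*.
    Returns a table with one row per event: event_id, emX, emY, emZ, n_op.
    """
    if activity <= 0 or duration <= 0:
        raise ValueError("activity and duration must be positive")
    yield_model = YieldModel() if yield_model is None else yield_model
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(activity * duration)
    n_op = rng.poisson(yield_model.mean_photons_per_event, size=n_events)
    point = np.asarray(emission_point, dtype=float)
    return pd.DataFrame(
        {
            "event_id": np.arange(n_events, dtype=np.int64),
            "emX": point[0],
            "emY": point[1],
            "emZ": point[2],
            "n_op": n_op.astype(np.int64),
        }
    )
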