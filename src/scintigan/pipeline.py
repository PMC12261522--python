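"""End-to-end surrogate pipeline: events in, phase-space table out.

Mirrors the fast-simulation workflow in which optical photons are
counted at creation but never tracked: a per-event log supplies each
event's photon count ``n_op`` and emission coordinates (the first
recorded electron position), the trained generator produces ``n_op``
feature rows per event conditioned on its emission point, and the
result is denormalized and written as an ordinary phase-space table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gan import Checkpoint, _net_from_params, _normalized_condition
from .optics import CrystalGeometry
from .phasespace import CONDITION_COLUMNS, FEATURE_COLUMNS, PHASESPACE_COLUMNS, denormalize

__all__ = [
    "ELECTRON",
    "OPTICAL_PHOTON",
    "EVENT_COLUMNS",
    "synthesize_event_log",
    "extract_emission_coordinates",
    "run_surrogate",
    "subsample",
]

ELECTRON = "e-"
OPTICAL_PHOTON = "opticalphoton"
EVENT_COLUMNS = ("event_id", "emX", "emY", "emZ", "n_op")


def synthesize_event_log(events: pd.DataFrame) -> pd.DataFrame:
    """Expand an event table into a per-step particle log.

    Each event contributes one electron record at step 0 located at the
    emission point followed by ``n_op`` optical-photon creation records
    (positions at the emission point; they are killed at creation, so
    no transport positions exist).  Useful as the in-package analog of
    an externally produced tracking log.
    """
    rows = []
    for ev in events.itertuples(index=False):
        rows.append((ev.event_id, ELECTRON, 0, ev.emX, ev.emY, ev.emZ))
        for k in range(int(ev.n_op)):
            rows.append((ev.event_id, OPTICAL_PHOTON, k + 1, ev.emX, ev.emY, ev.emZ))
    return pd.DataFrame(rows, columns=["event_id", "particle", "step", "x", "y", "z"])


def extract_emission_coordinates(event_log: pd.DataFrame) -> pd.DataFrame:
    """Per-event emission coordinates and photon counts from a step log.

    For every event the electron record with the smallest step index
    supplies (emX, emY, emZ); ``n_op`` counts that event's
    optical-photon records.  Events lacking any electron record are an
    error (there is no emission point to condition on).
    """
    required = {"event_id", "particle", "step", "x", "y", "z"}
    missing = required - set(event_log.columns)
    if missing:
        raise ValueError(f"event log is missing columns: {sorted(missing)}")

    all_events = pd.unique(event_log["event_id"])
    electrons = event_log[event_log["particle"] == ELECTRON]
    no_electron = sorted(
        x.item() if hasattr(x, "item") else x
        for x in set(all_events) - set(electrons["event_id"])
    )
    if no_electron:
        raise ValueError(f"events without an electron record: {no_electron}")

    first = electrons.sort_values("step", kind="stable").groupby("event_id", sort=False).first()
    photons = event_log[event_log["particle"] == OPTICAL_PHOTON]
    counts = photons.groupby("event_id").size()

    out = pd.DataFrame(
        {
            "event_id": all_events,
            "emX": first.loc[all_events, "x"].to_numpy(),
            "emY": first.loc[all_events, "y"].to_numpy(),
            "emZ": first.loc[all_events, "z"].to_numpy(),
            "n_op": counts.reindex(all_events, fill_value=0).to_numpy(dtype=np.int64),
        }
    )
    return out.reset_index(drop=True)


def run_surrogate(
    events: pd.DataFrame,
    checkpoint: Checkpoint,
    seed=None,
    geometry: CrystalGeometry | None = None,
    batch_rows: int = 65536,
    clip: bool = False,
) -> pd.DataFrame:
    """Generate a phase-space table for every photon of every event.

    The output has exactly ``sum(n_op)`` rows; each event's rows are
    generated with its normalized emission coordinates as the GAN
    condition and denormalized to physical units.  Latents for the
    whole request are drawn up front from the seeded generator, so
    batching cannot change the result.

    With ``clip=True`` generated positions are clamped to the detector
    face and directions renormalized to unit length; off by default to
    preserve the learned distribution.
    """
    if checkpoint.stats is None:
        raise ValueError("checkpoint carries no normalization statistics")
    geometry = CrystalGeometry() if geometry is None else geometry
    config = checkpoint.config

    for ev in events.itertuples(index=False):
        if not geometry.contains((ev.emX, ev.emY, ev.emZ)):
            raise ValueError(
                f"event {ev.event_id}: emission point ({ev.emX}, {ev.emY}, {ev.emZ}) "
                "lies outside the crystal"
            )

    n_op = events["n_op"].to_numpy(dtype=np.int64) if len(events) else np.array([], dtype=np.int64)
    total = int(n_op.sum())
    if total == 0:
        return pd.DataFrame({c: np.empty(0, dtype=float) for c in PHASESPACE_COLUMNS})

    points = events[["emX", "emY", "emZ"]].to_numpy(dtype=float)
    cond_phys = np.repeat(points, n_op, axis=0)
    cond_stats = checkpoint.stats.subset(CONDITION_COLUMNS)
    cond = ((cond_phys - cond_stats.mean) / cond_stats.std).astype(np.float32)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((total, config.latent_dim)).astype(np.float32)

    net = _net_from_params(checkpoint.generator_params)
    outs = []
    for start in range(0, total, batch_rows):
        sl = slice(start, min(start + batch_rows, total))
        outs.append(net.forward(np.concatenate([z[sl], cond[sl]], axis=1)))
    feats = np.concatenate(outs, axis=0)

    table = pd.DataFrame(np.asarray(feats, dtype=float), columns=list(FEATURE_COLUMNS))
    table = denormalize(table, checkpoint.stats.subset(FEATURE_COLUMNS))
    if clip:
        table["X"] = table["X"].clip(-geometry.half_width_x, geometry.half_width_x)
        table["Y"] = table["Y"].clip(-geometry.half_width_y, geometry.half_width_y)
        d = table[["dX", "dY", "dZ"]].to_numpy()
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        table[["dX", "dY", "dZ"]] = d / norm
    table["emX"] = cond_phys[:, 0]
    table["emY"] = cond_phys[:, 1]
    table["emZ"] = cond_phys[:, 2]
    return table


def subsample(table: pd.DataFrame, n: int, seed=None) -> pd.DataFrame:
    """Uniform without-replacement sample of exactly ``n`` rows."""
    if n > len(table):
        raise ValueError(f"cannot subsample {n} rows from a table of {len(table)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=False)
    return table.iloc[idx].reset_index(drop=True)
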