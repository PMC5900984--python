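"""PGSE acquisition protocols and diffusion-weighting (b-value) arithmetic.

A pulsed-gradient spin-echo (PGSE) measurement is described by the gradient
amplitude ``G`` (mT/m), pulse duration ``delta`` (ms) and pulse separation
``Delta`` (ms).  For ideal rectangular pulses the diffusion weighting is

    b = gamma^2 G^2 delta^2 (Delta - delta/3)

reported here in s/mm^2.  All public quantities use the units conventional in
the field (mT/m, ms, s/mm^2, um^2/ms); conversion to SI happens internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GYROMAGNETIC_RATIO_PROTON",
    "PGSEMeasurement",
    "Protocol",
    "InvalidProtocolError",
    "compute_b",
    "make_reference_protocols",
    "validate_protocol",
    "read_protocol_table",
    "write_protocol_table",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GYROMAGNETIC_RATIO_PROTON = 2.6752218744e8


class InvalidProtocolError(ValueError):
    """Raised when PGSE timing parameters or a protocol table are inconsistent."""


def compute_b(
    G: float,
    delta: float,
    Delta: float,
    gamma: float = GYROMAGNETIC_RATIO_PROTON,
) -> float:
    """Diffusion weighting b = gamma^2 G^2 delta^2 (Delta - delta/3), in s/mm^2.

    Parameters
    ----------
    G : gradient amplitude in mT/m.
    delta : gradient pulse duration in ms.
    Delta : gradient pulse separation in ms; must satisfy 0 < delta <= Delta.
    gamma : gyromagnetic ratio in rad s^-1 T^-1.
    """
    G = float(G)
    delta = float(delta)
    Delta = float(Delta)
    if G < 0:
        raise InvalidProtocolError(f"negative gradient amplitude G={G}")
    if delta <= 0:
        raise InvalidProtocolError(f"non-positive pulse duration delta={delta}")
    if delta > Delta:
        raise InvalidProtocolError(f"delta={delta} ms exceeds Delta={Delta} ms")
    G_si = G * 1e-3          # T/m
    d_si = delta * 1e-3      # s
    D_si = Delta * 1e-3      # s
    b_si = gamma**2 * G_si**2 * d_si**2 * (D_si - d_si / 3.0)  # s/m^2
    return b_si * 1e-6       # s/mm^2


@dataclass(frozen=True)
class PGSEMeasurement:
    """One PGSE acquisition: gradient amplitude and timing, plus TE/TR metadata.

    ``TE``/``TR`` are carried along for bookkeeping (e.g. per-Delta amplitude
    differences from T2 decay) but never enter the diffusion model.
    """

    G: float                 # mT/m
    delta: float             # ms
    Delta: float             # ms
    TE: float | None = None  # ms, metadata only
    TR: float | None = None  # ms, metadata only

    def __post_init__(self) -> None:
        if self.G < 0:
            raise InvalidProtocolError(f"negative gradient amplitude G={self.G}")
        if not (0 < self.delta <= self.Delta):
            raise InvalidProtocolError(
                f"require 0 < delta <= Delta, got delta={self.delta}, Delta={self.Delta}"
            )

    def b(self, gamma: float = GYROMAGNETIC_RATIO_PROTON) -> float:
        """Diffusion weighting of this measurement in s/mm^2."""
        return compute_b(self.G, self.delta, self.Delta, gamma)


@dataclass(frozen=True)
class Protocol:
    """Ordered sequence of PGSE measurements; order indexes the 4th image axis."""

    measurements: tuple[PGSEMeasurement, ...]
    gamma: float = GYROMAGNETIC_RATIO_PROTON

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def __getitem__(self, i: int) -> PGSEMeasurement:
        return self.measurements[i]

    @property
    def b_values(self) -> np.ndarray:
        """b-values (s/mm^2) in measurement order."""
        return np.array([m.b(self.gamma) for m in self.measurements])

    @property
    def G_values(self) -> np.ndarray:
        return np.array([m.G for m in self.measurements])

    @property
    def Delta_values(self) -> np.ndarray:
        return np.array([m.Delta for m in self.measurements])

    @property
    def delta_values(self) -> np.ndarray:
        return np.array([m.delta for m in self.measurements])

    def delta_groups(self) -> dict[float, np.ndarray]:
        """Measurement indices grouped by Delta, keyed by the Delta value (ms)."""
        groups: dict[float, list[int]] = {}
        for i, m in enumerate(self.measurements):
            groups.setdefault(m.Delta, []).append(i)
        return {k: np.array(v) for k, v in sorted(groups.items())}

    def subset(self, indices: Sequence[int]) -> "Protocol":
        """New protocol restricted to the given measurement indices (order kept)."""
        return Protocol(tuple(self.measurements[i] for i in indices), self.gamma)

    def drop_longest_delta(self) -> "Protocol":
        """Protocol excluding all measurements at the longest diffusion time."""
        longest = max(m.Delta for m in self.measurements)
        keep = [i for i, m in enumerate(self.measurements) if m.Delta != longest]
        return self.subset(keep)


def make_reference_protocols(
    gamma: float = GYROMAGNETIC_RATIO_PROTON,
) -> tuple[Protocol, Protocol]:
    """Factory for the two preclinical 7 T protocols the package targets.

    Returns ``(adc_protocol, microstructure_protocol)``:

    * ADC protocol: a four-point b-ladder (nominally 0, 150, 500, 1000 s/mm^2)
      at Delta = 12 ms (G = 0, 117.6, 214.7, 303.7 mT/m, TE = 21.3 ms) and at
      Delta = 45 ms (G = 0, 58.3, 106.4, 150.5 mT/m, TE = 54.3 ms), delta = 4 ms.
    * Microstructure protocol: G = 0, 70, 140, 210 mT/m at each of
      Delta = 12, 23, 45 ms, delta = 4 ms (TE = 21.3, 32.3, 54.3 ms).

    TR = 2500 ms throughout.  b-values are always recomputed from (G, delta,
    Delta, gamma); the nominal ladder is not used numerically.
    """
    TR = 2500.0
    adc = []
    for Delta, TE, Gs in [
        (12.0, 21.3, (0.0, 117.6, 214.7, 303.7)),
        (45.0, 54.3, (0.0, 58.3, 106.4, 150.5)),
    ]:
        for G in Gs:
            adc.append(PGSEMeasurement(G=G, delta=4.0, Delta=Delta, TE=TE, TR=TR))
    micro = []
    for Delta, TE in [(12.0, 21.3), (23.0, 32.3), (45.0, 54.3)]:
        for G in (0.0, 70.0, 140.0, 210.0):
            micro.append(PGSEMeasurement(G=G, delta=4.0, Delta=Delta, TE=TE, TR=TR))
    return Protocol(tuple(adc), gamma), Protocol(tuple(micro), gamma)


def validate_protocol(
    p: Protocol,
    n_volumes: int | None = None,
    require_normalization: bool = False,
) -> Protocol:
    """Validate a protocol; return it unchanged or raise :class:`InvalidProtocolError`.

    A missing G = 0 measurement for some Delta is a warning unless
    ``require_normalization`` is set (per-Delta normalization needs the G = 0
    reference), in which case it is fatal.  A mismatch between the measurement
    count and ``n_volumes`` (the image's 4th-axis length) is fatal.
    """
    if len(p) == 0:
        raise InvalidProtocolError("protocol has no measurements")
    for m in p:
        # PGSEMeasurement invariants re-checked in case of pickled/forged objects
        if m.G < 0 or not (0 < m.delta <= m.Delta):
            raise InvalidProtocolError(f"invalid measurement {m}")
    if n_volumes is not None and n_volumes != len(p):
        raise InvalidProtocolError(
            f"protocol has {len(p)} measurements but image has {n_volumes} volumes"
        )
    missing = [D for D, idx in p.delta_groups().items() if not np.any(p.G_values[idx] == 0)]
    if missing:
        msg = f"no G=0 measurement for Delta={missing} ms; per-Delta normalization impossible"
        if require_normalization:
            raise InvalidProtocolError(msg)
        warnings.warn(msg, stacklevel=2)
    return p


_TABLE_COLUMNS = ["volume_index", "G_mT_per_m", "delta_ms", "Delta_ms", "TE_ms", "TR_ms"]


def read_protocol_table(path: str | Path, gamma: float = GYROMAGNETIC_RATIO_PROTON) -> Protocol:
    """Read a protocol from a CSV/TSV table or a JSON/YAML file.

    Tables need columns [volume_index, G_mT_per_m, delta_ms, Delta_ms] with
    optional TE_ms/TR_ms.  An optional ``b_s_per_mm2`` column is treated as a
    cross-check only: a warning is issued if it disagrees with the rectangular
    PGSE formula by more than 2%, and the recomputed value is used regardless.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".yaml", ".yml"}:
        if path.suffix.lower() == ".json":
            records = json.loads(path.read_text())
        else:
            import yaml

            records = yaml.safe_load(path.read_text())
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    for col in ["G_mT_per_m", "delta_ms", "Delta_ms"]:
        if col not in df.columns:
            raise InvalidProtocolError(f"protocol table missing column {col!r}")
    if "volume_index" in df.columns:
        df = df.sort_values("volume_index")
    meas = []
    for _, row in df.iterrows():
        meas.append(
            PGSEMeasurement(
                G=float(row["G_mT_per_m"]),
                delta=float(row["delta_ms"]),
                Delta=float(row["Delta_ms"]),
                TE=float(row["TE_ms"]) if "TE_ms" in df.columns and pd.notna(row["TE_ms"]) else None,
                TR=float(row["TR_ms"]) if "TR_ms" in df.columns and pd.notna(row["TR_ms"]) else None,
            )
        )
    proto = Protocol(tuple(meas), gamma)
    if "b_s_per_mm2" in df.columns:
        stated = df["b_s_per_mm2"].to_numpy(dtype=float)
        computed = proto.b_values
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(stated - computed) / np.where(computed > 0, computed, 1.0)
        bad = (rel > 0.02) & ~((stated == 0) & (computed == 0))
        if np.any(bad):
            warnings.warn(
                "stated b-values disagree with gamma^2 G^2 delta^2 (Delta - delta/3) "
                f"by >2% for volumes {np.nonzero(bad)[0].tolist()}; "
                "recomputed values are used",
                stacklevel=2,
            )
    return proto


def write_protocol_table(p: Protocol, path: str | Path) -> None:
    """Write a protocol as a CSV table (one row per volume, in order)."""
    rows = []
    for i, m in enumerate(p):
        rows.append(
            {
                "volume_index": i,
                "G_mT_per_m": m.G,
                "delta_ms": m.delta,
                "Delta_ms": m.Delta,
                "TE_ms": m.TE if m.TE is not None else "",
                "TR_ms": m.TR if m.TR is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)
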