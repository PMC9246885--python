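"""Synthetic microarray scan generator.

Emulates the signal structure of the fluorescence scans the quantification
module analyses, so every estimator is testable without instrument data.

Signal model per feature (hybridization mode)::

    F = A * e * s(L) * r_arm * eps + B,   s(L) = L / (K + L)

where ``A`` is the saturated amplitude, ``e`` the DNA->RNA conversion
efficiency (controls hybridize directly, so e = 1 for them; untreated arms
have no RNA, so templates read background only), ``s`` a saturating
duplex-length response for probe-overlap length ``L``, ``r_arm`` the
residual factor of a degradation arm, ``eps`` multiplicative lognormal
noise of the configured CV, and ``B`` a background draw around ``b``.

Cy3-UTP mode replaces ``s(L)`` by a distance-decay profile
``d(pos) = max(decay**(pos-1), plateau)`` evaluated at the probe's annotated
rU extension position — fluorophores far from the glass report less signal,
flattening to a plateau; untranscribable controls carry no rU and read
background only (non-specific label binding).

Deliberately absent from the model: spatial artifacts (gradients,
scratches), optical point-spread and scanner saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import DesignTable
from .imagecode import ArrayLayout

__all__ = ["SimParams", "Arm", "ScanTable", "SimulationError", "simulate_scan"]


class SimulationError(ValueError):
    """A layout probe cannot be simulated (unknown id or role)."""


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of the scan simulator.

    Parameters
    ----------
    seed : int
        Mandatory seed for the noise generator.
    amplitude : float
        Saturated specific signal, arbitrary fluorescence units.
    half_saturation : float
        Half-saturation overlap length K (nt) of the duplex response.
    decay, plateau : float
        Per-nt decay factor and terminal plateau fraction of the Cy3-UTP
        distance profile (plateau relative to extension position 1).
    efficiency : float
        DNA->RNA conversion efficiency e in [0, 1].
    background : float
        Mean background intensity b.
    cv : float
        Coefficient of variation of the multiplicative lognormal noise.
    mode : str
        ``"hybridization"`` (duplex-length response) or ``"cy3_utp"``
        (positional incorporation profile).
    """

    seed: int
    amplitude: float = 10_000.0
    half_saturation: float = 8.0
    decay: float = 0.96
    plateau: float = 0.70
    efficiency: float = 0.20
    background: float = 100.0
    cv: float = 0.2
    mode: str = "hybridization"

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")
        if not 0.0 <= self.plateau <= 1.0:
            raise ValueError("plateau must be in [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.mode not in ("hybridization", "cy3_utp"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Arm:
    """One treatment condition of a simulated experiment.

    ``converted`` — whether the arm underwent primer extension (RNA present
    on templates); ``residual`` — surviving fraction of specific signal
    after a degradation treatment (1.0 for buffer controls).
    """

    name: str
    converted: bool = True
    residual: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual <= 1.0:
            raise ValueError("residual must be in [0, 1]")


@dataclass
class ScanTable:
    """Per-feature intensities for one scanned arm/channel."""

    frame: pd.DataFrame  # columns: row, col, probe_id, channel, F, B

    def __len__(self) -> int:
        return len(self.frame)

    def values_for(self, probe_id: str, channel: Optional[int] = None) -> np.ndarray:
        sel = self.frame["probe_id"] == probe_id
        if channel is not None:
            sel &= self.frame["channel"] == channel
        return self.frame.loc[sel, "F"].to_numpy(dtype=float)

    def probe_ids(self) -> List[str]:
        return sorted(self.frame["probe_id"].unique())


def _expected_specific(template, params: SimParams, arm: Arm) -> float:
    """Noise-free specific (above-background) signal for one probe."""
    if params.mode == "cy3_utp":
        if template.role != "transcribable" or not arm.converted:
            return 0.0
        pos = template.ru_position
        if pos is None:
            raise SimulationError(
                f"probe {template.probe_id!r}: cy3_utp mode needs an rU position annotation"
            )
        d = max(params.decay ** (pos - 1), params.plateau)
        return params.amplitude * d * arm.residual
    # hybridization mode
    L = template.effective_response_len
    s = L / (params.half_saturation + L) if L > 0 else 0.0
    if template.role == "transcribable":
        if not arm.converted:
            return 0.0  # no RNA made; template strand itself is not probe-complementary
        return params.amplitude * params.efficiency * s * arm.residual
    if template.role == "control":
        return params.amplitude * 1.0 * s * arm.residual
    raise SimulationError(f"probe {template.probe_id!r}: unknown role {template.role!r}")


def simulate_scan(
    layout: ArrayLayout,
    design: DesignTable,
    params: SimParams,
    arms: Sequence[Arm] = (Arm("default"),),
    channel: int = 532,
) -> Dict[str, ScanTable]:
    """Generate one ScanTable per arm.

    Deterministic given ``params.seed`` and the arm list; with ``cv = 0``
    and ``background`` noise-free the foreground equals the closed-form
    expectation exactly.
    """
    index = design.index()
    rng = np.random.default_rng(params.seed)
    positions = sorted(layout.features)
    templates = []
    for pos in positions:
        pid = layout.features[pos]
        if pid not in index:
            raise SimulationError(f"probe {pid!r} at {pos} not in design table")
        templates.append(index[pid])
    out: Dict[str, ScanTable] = {}
    sigma = float(np.sqrt(np.log1p(params.cv**2)))
    for arm in arms:
        n = len(positions)
        mu = np.array([_expected_specific(t, params, arm) for t in templates])
        if params.cv > 0:
            eps = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
        else:
            eps = np.ones(n)
        if params.cv > 0 and params.background > 0:
            bg = rng.normal(params.background, params.cv * params.background, size=n)
            bg = np.clip(bg, 0.0, None)
        else:
            bg = np.full(n, params.background)
        fg = mu * eps + bg
        frame = pd.DataFrame(
            {
                "row": [p[0] for p in positions],
                "col": [p[1] for p in positions],
                "probe_id": [t.probe_id for t in templates],
                "channel": channel,
                "F": fg,
                "B": bg,
            }
        )
        out[arm.name] = ScanTable(frame)
    return out
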