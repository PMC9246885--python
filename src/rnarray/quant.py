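"""Scan quantification: replicate aggregation, control subtraction,
max-normalization, and the ratio estimators of the conversion workflow.

The one fully specified recipe is followed throughout: replicate
foregrounds are averaged per probe; averaged control-probe signal is
subtracted from the matched template signal (flooring at zero — negative
corrected intensities are not meaningful); corrected values are normalized
to the highest corrected signal. Ratio estimators (conversion efficiency,
degradation residual) are ratios of replicate means with seeded bootstrap
confidence intervals, since no analytic error model is available for
scanner ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import DesignTable
from .scansim import ScanTable

__all__ = [
    "QuantError",
    "DegenerateNormalizationError",
    "UndefinedRatioError",
    "MissingReferenceError",
    "aggregate",
    "background_correct_normalize",
    "RatioEstimate",
    "RatioReport",
    "conversion_efficiency",
    "degradation_residual",
    "PositionalProfile",
    "positional_profile",
]


class QuantError(ValueError):
    pass


class DegenerateNormalizationError(QuantError):
    """All corrected intensities are <= 0; normalization undefined."""


class UndefinedRatioError(QuantError):
    """The denominator arm has non-positive mean signal."""


class MissingReferenceError(QuantError):
    """The reference (position-1) variant is absent from the scan."""


def _as_frame(scan) -> pd.DataFrame:
    return scan.frame if isinstance(scan, ScanTable) else pd.DataFrame(scan)


def replicate_values(scan, channel: Optional[int] = None) -> Dict[str, np.ndarray]:
    """Per-probe arrays of foreground replicate values."""
    frame = _as_frame(scan)
    if channel is not None:
        frame = frame[frame["channel"] == channel]
    return {
        pid: grp["F"].to_numpy(dtype=float) for pid, grp in frame.groupby("probe_id")
    }


def aggregate(
    scan,
    design: Optional[DesignTable] = None,
    exclude: str = "none",
    mad_m: float = 5.0,
    channel: Optional[int] = None,
) -> pd.DataFrame:
    """Per-probe replicate statistics (mean, sd of foreground).

    ``exclude="mad"`` switches on the dust rule: replicates more than
    ``mad_m`` median absolute deviations *above* the probe median (dust
    causes extraordinarily high signal, not low) are excluded and counted in
    ``n_excluded``. Default is off: ordinarily no data are excluded.

    Probes present in ``design`` but absent from the scan are dropped from
    the report (a warning is attached to the frame attrs).
    """
    if exclude not in ("none", "mad"):
        raise ValueError(f"unknown exclusion rule {exclude!r}")
    values = replicate_values(scan, channel=channel)
    missing: List[str] = []
    if design is not None:
        missing = [t.probe_id for t in design if t.probe_id not in values]
    rows = []
    for pid in sorted(values):
        x = values[pid]
        n_excluded = 0
        if exclude == "mad" and len(x) >= 3:
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            if mad > 0:
                keep = x <= med + mad_m * mad
                n_excluded = int((~keep).sum())
                x = x[keep]
        rows.append(
            {
                "probe_id": pid,
                "n_replicates": len(x) + n_excluded,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "n_excluded": n_excluded,
            }
        )
    out = pd.DataFrame(rows).set_index("probe_id")
    out.attrs["missing_probes"] = missing
    return out


def background_correct_normalize(
    template_means: Mapping[str, float],
    control_means: Mapping[str, float],
    pairing: Mapping[str, str],
) -> pd.DataFrame:
    """Subtract matched control means and normalize to the maximum.

    ``corrected_i = max(template_i - control_i, 0)``;
    ``normalized_i = corrected_i / max_j corrected_j``. Shift-invariant in
    any constant added to both arms.
    """
    rows = []
    for tid, cid in pairing.items():
        corrected = max(float(template_means[tid]) - float(control_means[cid]), 0.0)
        rows.append({"probe_id": tid, "control_id": cid, "corrected": corrected})
    frame = pd.DataFrame(rows).set_index("probe_id")
    top = frame["corrected"].max()
    if not top > 0:
        raise DegenerateNormalizationError(
            "all corrected intensities are <= 0; nothing to normalize to"
        )
    frame["normalized"] = frame["corrected"] / top
    return frame


@dataclass(frozen=True)
class RatioEstimate:
    name: str
    ratio: float
    ci_low: float
    ci_high: float
    n_num: int
    n_den: int


@dataclass
class RatioReport:
    """Per-pair ratio estimates plus a pooled summary, all with bootstrap CIs."""

    per_pair: List[RatioEstimate]
    summary: RatioEstimate
    scale: float  # 100.0 for percentages, 1.0 for fractions

    def to_frame(self) -> pd.DataFrame:
        rows = [e.__dict__ for e in self.per_pair + [self.summary]]
        return pd.DataFrame(rows).set_index("name")


def _resample_mean(rng, x: np.ndarray) -> float:
    return float(np.mean(x[rng.integers(0, len(x), len(x))]))


def _ratio_estimator(
    num_values: Mapping[str, np.ndarray],
    den_values: Mapping[str, np.ndarray],
    pairing: Mapping[str, str],
    scale: float,
    n_boot: int,
    seed: int,
    summary_name: str,
    num_background: Optional[np.ndarray] = None,
    den_background: Optional[np.ndarray] = None,
) -> RatioReport:
    rng = np.random.default_rng(seed)
    pairs = list(pairing.items())
    nb = np.asarray(num_background, dtype=float) if num_background is not None else None
    db = np.asarray(den_background, dtype=float) if den_background is not None else None
    nb_mean = float(np.mean(nb)) if nb is not None else 0.0
    db_mean = float(np.mean(db)) if db is not None else 0.0
    nums = []
    dens = []
    for nid, did in pairs:
        x = np.asarray(num_values[nid], dtype=float)
        y = np.asarray(den_values[did], dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise QuantError(f"pair ({nid}, {did}): empty replicate set")
        if np.mean(y) - db_mean <= 0:
            raise UndefinedRatioError(f"pair ({nid}, {did}): denominator mean <= 0")
        nums.append(x)
        dens.append(y)
    point = [
        scale * (np.mean(x) - nb_mean) / (np.mean(y) - db_mean)
        for x, y in zip(nums, dens)
    ]
    # bootstrap replicate means within each pair (and the background pools)
    boot = np.empty((n_boot, len(pairs)))
    for b in range(n_boot):
        bn = _resample_mean(rng, nb) if nb is not None else 0.0
        bd = _resample_mean(rng, db) if db is not None else 0.0
        for j, (x, y) in enumerate(zip(nums, dens)):
            xm = _resample_mean(rng, x) - bn
            ym = _resample_mean(rng, y) - bd
            boot[b, j] = scale * xm / ym if ym > 0 else np.nan
    per_pair = []
    for j, (nid, did) in enumerate(pairs):
        lo, hi = np.nanpercentile(boot[:, j], [2.5, 97.5])
        per_pair.append(
            RatioEstimate(f"{nid}/{did}", point[j], float(lo), float(hi), len(nums[j]), len(dens[j]))
        )
    summary_boot = np.nanmean(boot, axis=1)
    lo, hi = np.nanpercentile(summary_boot, [2.5, 97.5])
    summary = RatioEstimate(
        summary_name,
        float(np.mean(point)),
        float(lo),
        float(hi),
        int(np.mean([len(x) for x in nums])),
        int(np.mean([len(y) for y in dens])),
    )
    return RatioReport(per_pair, summary, scale)


def conversion_efficiency(
    rna_scan,
    dna_scan,
    pairing: Mapping[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    channel: Optional[int] = None,
    background_probe: Optional[str] = None,
) -> RatioReport:
    """Conversion efficiency (%) of the DNA->RNA process.

    For each pair, the mean hybridization signal on converted RNA features
    (treated subarray) is divided by the mean signal on the matched
    single-stranded DNA reference features (untreated subarray) and expressed
    as a percentage, with a seeded bootstrap CI over replicates.

    If ``background_probe`` names a non-hybridizing feature class, its
    averaged signal in each arm is subtracted from the replicate means first
    (the control-subtraction recipe); otherwise raw means are ratioed.
    """
    rna_values = replicate_values(rna_scan, channel)
    dna_values = replicate_values(dna_scan, channel)
    return _ratio_estimator(
        rna_values,
        dna_values,
        pairing,
        scale=100.0,
        n_boot=n_boot,
        seed=seed,
        summary_name="efficiency_pct",
        num_background=rna_values.get(background_probe) if background_probe else None,
        den_background=dna_values.get(background_probe) if background_probe else None,
    )


def degradation_residual(
    treated_scan,
    buffer_scan,
    pairing: Mapping[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    channel: Optional[int] = None,
    background_probe: Optional[str] = None,
) -> RatioReport:
    """Residual signal fraction after a degradation treatment.

    ``residual = mean(treated) / mean(buffer)`` per probe class, normalized
    to the buffer-incubated control arm; same bootstrap contract (and
    optional background-probe subtraction) as
    :func:`conversion_efficiency` but reported as a fraction.
    """
    treated_values = replicate_values(treated_scan, channel)
    buffer_values = replicate_values(buffer_scan, channel)
    return _ratio_estimator(
        treated_values,
        buffer_values,
        pairing,
        scale=1.0,
        n_boot=n_boot,
        seed=seed,
        summary_name="residual",
        num_background=treated_values.get(background_probe) if background_probe else None,
        den_background=buffer_values.get(background_probe) if background_probe else None,
    )


@dataclass
class PositionalProfile:
    """Relative labelled-rU intensity versus extension position."""

    profile: pd.DataFrame  # columns: position, corrected, normalized, relative
    final_window_mean: float
    window_nt: int

    @property
    def positions(self) -> np.ndarray:
        return self.profile["position"].to_numpy()


def positional_profile(
    scan,
    design: DesignTable,
    exclude: str = "none",
    mad_m: float = 5.0,
    window_nt: int = 20,
    channel: Optional[int] = None,
) -> PositionalProfile:
    """Quantify a single-dA walk scan into a positional synthesis profile.

    Replicates are aggregated, matched no-primer-complement controls (same
    rU position annotation) are subtracted, corrected values are normalized
    to the maximum, and every variant is re-expressed relative to the
    position-1 (surface-proximal) variant. ``final_window_mean`` averages
    the relative intensities of variants whose rU lies within the final
    ``window_nt`` nucleotides of the product — the plateau statistic.
    """
    stats = aggregate(scan, design, exclude=exclude, mad_m=mad_m, channel=channel)
    by_pos_t: Dict[int, str] = {}
    by_pos_c: Dict[int, str] = {}
    for t in design:
        if t.ru_position is None or t.probe_id not in stats.index:
            continue
        if t.role == "transcribable":
            by_pos_t[t.ru_position] = t.probe_id
        else:
            by_pos_c[t.ru_position] = t.probe_id
    if 1 not in by_pos_t:
        raise MissingReferenceError("position-1 variant missing from scan/design")
    pairing = {
        by_pos_t[pos]: by_pos_c[pos] for pos in by_pos_t if pos in by_pos_c
    }
    if not pairing:
        raise QuantError("no template/control pairs with rU annotations found")
    corrected = background_correct_normalize(
        stats["mean"].to_dict(), stats["mean"].to_dict(), pairing
    )
    pos_of = {pid: pos for pos, pid in by_pos_t.items()}
    corrected = corrected.assign(position=[pos_of[pid] for pid in corrected.index])
    corrected = corrected.sort_values("position").reset_index()
    ref = corrected.loc[corrected["position"] == 1, "corrected"]
    if ref.empty or not ref.iloc[0] > 0:
        raise MissingReferenceError("position-1 variant has no positive corrected signal")
    corrected["relative"] = corrected["corrected"] / float(ref.iloc[0])
    max_pos = int(corrected["position"].max())
    in_window = corrected["position"] > max_pos - window_nt
    final_mean = float(corrected.loc[in_window, "relative"].mean())
    profile = corrected[["position", "corrected", "normalized", "relative"]]
    return PositionalProfile(profile, final_mean, window_nt)
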