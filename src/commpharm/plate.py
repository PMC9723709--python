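"""Plate-reader assay pipeline.

Ingests microtitre-plate time series (optical density at 600 nm plus
per-strain fluorescence channels), blank-corrects them, converts
fluorescence to estimated optical density (eOD) through a calibration
ratio measured in pure culture, and derives replicate-wise IC90s with
95% confidence intervals. Conditions are compared with an exact
Wilcoxon-Mann-Whitney rank-sum test, and relative drug content per cell
is estimated as culture density at the IC90 divided by the IC90
concentration.

Plate files are long-format delimited text (well, time_h, channel,
value); the layout file is YAML mapping each well to its metadata
(strains, drug concentration, replicate, blank flag) plus the
strain-to-channel table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "PlateTimeSeries",
    "WellMeta",
    "CalibrationResult",
    "Ic90Estimate",
    "MannWhitneyResult",
    "PlateFormatError",
    "read_plate",
    "write_plate",
    "read_layout",
    "write_layout",
    "blank_correct",
    "calibrate_fluorescence",
    "estimated_od",
    "empirical_ic90",
    "exact_mann_whitney",
    "relative_drug_content",
]

CHANNELS = ("OD600", "YFP", "CFP")
ENDPOINT_H = 24.0
DETECTION_SD = 3.0  # readings below DETECTION_SD * blank sd are excluded


class PlateFormatError(ValueError):
    """Malformed plate file or layout."""


@dataclass(frozen=True)
class WellMeta:
    """Metadata for one well: strains present, dose, replicate, blank."""

    strains: tuple[str, ...]
    concentration: float | None
    replicate: int
    blank: bool = False

    @property
    def composition(self) -> str:
        if self.blank:
            return "blank"
        if len(self.strains) == 1:
            return f"pure-{self.strains[0]}"
        return "mixed"


@dataclass
class PlateTimeSeries:
    """Well x time x channel measurements plus per-well metadata."""

    wells: list[str]
    times: np.ndarray
    channels: list[str]
    values: np.ndarray  # (n_wells, n_times, n_channels)
    metadata: dict[str, WellMeta]
    strain_channels: dict[str, str] = field(default_factory=dict)
    blank_corrected: bool = False
    blank_sd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.wells), len(self.times),
                                 len(self.channels)):
            raise PlateFormatError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.wells)} wells x {len(self.times)} times x "
                f"{len(self.channels)} channels")
        if np.any(np.diff(self.times) <= 0):
            raise PlateFormatError("times must be strictly increasing")
        missing = [w for w in self.wells if w not in self.metadata]
        if missing:
            raise PlateFormatError(f"wells without metadata: {missing}")
        if not any(m.blank for m in self.metadata.values()):
            raise PlateFormatError("plate has no blank wells")
        for w, m in self.metadata.items():
            if not m.blank and m.concentration is None:
                raise PlateFormatError(f"non-blank well {w} lacks a "
                                       "drug concentration")

    # -- selection helpers -------------------------------------------------
    def well_index(self, well: str) -> int:
        return self.wells.index(well)

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise PlateFormatError(
                f"channel {channel!r} not on plate {self.channels}") from None

    def select_wells(self, strain: str | None = None,
                     composition: str | None = None,
                     replicate: int | None = None,
                     blank: bool | None = None) -> list[str]:
        """Wells matching the given criteria.

        ``composition`` accepts 'pure', 'mixed', 'blank' or an explicit
        'pure-<strain>' label; 'pure'/'mixed' combine with ``strain``.
        """
        out = []
        for w in self.wells:
            m = self.metadata[w]
            if blank is not None and m.blank != blank:
                continue
            if strain is not None and strain not in m.strains:
                continue
            if composition is not None:
                comp = m.composition
                if composition == "pure":
                    if not comp.startswith("pure-"):
                        continue
                elif comp != composition:
                    continue
            if replicate is not None and m.replicate != replicate:
                continue
            out.append(w)
        return out

    def series(self, well: str, channel: str) -> np.ndarray:
        return self.values[self.well_index(well), :,
                           self.channel_index(channel)]

    def endpoint_index(self, at_time: float = ENDPOINT_H) -> int:
        """Grid point nearest the assay endpoint."""
        return int(np.argmin(np.abs(self.times - at_time)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (well, time_h, channel, value) table."""
        w, t, c = np.meshgrid(np.arange(len(self.wells)),
                              np.arange(len(self.times)),
                              np.arange(len(self.channels)), indexing="ij")
        return pd.DataFrame({
            "well": np.array(self.wells)[w.ravel()],
            "time_h": self.times[t.ravel()],
            "channel": np.array(self.channels)[c.ravel()],
            "value": self.values.ravel(),
        })


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_layout(plate: PlateTimeSeries, path: str | Path) -> None:
    doc = {
        "strain_channels": dict(plate.strain_channels),
        "wells": {
            w: {"strains": list(m.strains),
                "concentration": m.concentration,
                "replicate": m.replicate,
                "blank": m.blank}
            for w, m in plate.metadata.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_layout(path: str | Path):
    doc = yaml.safe_load(Path(path).read_text())
    try:
        wells = {
            w: WellMeta(strains=tuple(m.get("strains", []) or []),
                        concentration=m.get("concentration"),
                        replicate=int(m.get("replicate", 0)),
                        blank=bool(m.get("blank", False)))
            for w, m in doc["wells"].items()}
    except (KeyError, TypeError) as exc:
        raise PlateFormatError(f"{path}: malformed layout ({exc})") from exc
    return wells, dict(doc.get("strain_channels", {}))


def write_plate(plate: PlateTimeSeries, path: str | Path,
                sep: str = ",") -> None:
    """Long-format delimited plate file with a units header comment."""
    with open(path, "w") as fh:
        fh.write("# plate-reader time series: time_h in hours, OD600 in "
                 "OD units, fluorescence in arbitrary units\n")
        plate.to_frame().to_csv(fh, sep=sep, index=False)


def read_plate(path: str | Path, layout: str | Path | tuple,
               sep: str = ",", time_tol: float = 1e-6) -> PlateTimeSeries:
    """Parse a long-format plate file against a layout.

    ``layout`` is a layout-file path or a pre-parsed
    ``(well_metadata, strain_channels)`` pair. Wells absent from the
    layout, duplicate (well, time, channel) rows, missing channels and
    a non-uniform time grid are all rejected.
    """
    if isinstance(layout, (str, Path)):
        metadata, strain_channels = read_layout(layout)
    else:
        metadata, strain_channels = layout

    df = pd.read_csv(path, sep=sep, comment="#",
                     float_precision="round_trip")
    required = {"well", "time_h", "channel", "value"}
    if not required.issubset(df.columns):
        raise PlateFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")

    unmapped = sorted(set(df["well"]) - set(metadata))
    if unmapped:
        raise PlateFormatError(f"wells not in layout: {unmapped}")
    if df.duplicated(["well", "time_h", "channel"]).any():
        dups = df[df.duplicated(["well", "time_h", "channel"])]
        raise PlateFormatError(
            f"duplicate well-time rows, e.g. {dups.iloc[0].tolist()}")

    wells = sorted(set(df["well"]))
    times = np.array(sorted(set(df["time_h"])), dtype=float)
    steps = np.diff(times)
    if len(steps) and np.max(np.abs(steps - steps.mean())) > max(
            time_tol, 1e-9 * steps.mean()):
        raise PlateFormatError("non-uniform time grid")
    channels = [c for c in CHANNELS if c in set(df["channel"])]
    channels += [c for c in sorted(set(df["channel"])) if c not in channels]
    for ch in strain_channels.values():
        if ch not in channels:
            raise PlateFormatError(f"strain channel {ch!r} missing from file")

    cube = df.pivot_table(index="well", columns=["time_h", "channel"],
                          values="value")
    n_expected = len(times) * len(channels)
    if cube.isna().any().any() or cube.shape[1] != n_expected:
        raise PlateFormatError("incomplete well x time x channel grid")
    values = np.empty((len(wells), len(times), len(channels)))
    for k, ch in enumerate(channels):
        sub = cube.loc[wells, pd.IndexSlice[:, ch]]
        sub = sub.sort_index(axis=1)
        values[:, :, k] = sub.to_numpy()

    return PlateTimeSeries(wells=wells, times=times, channels=channels,
                           values=values,
                           metadata={w: metadata[w] for w in wells},
                           strain_channels=strain_channels)


# ---------------------------------------------------------------------------
# Corrections and calibration
# ---------------------------------------------------------------------------

def blank_correct(plate: PlateTimeSeries) -> PlateTimeSeries:
    """Subtract the time-matched mean of blank wells, per channel.

    Corrected values are floored at 0. Blank wells are retained (their
    corrected values hover near 0); the per-channel standard deviation
    of the blank readings is stored for detection-floor decisions.
    """
    blanks = [plate.well_index(w) for w in plate.select_wells(blank=True)]
    if not blanks:
        raise PlateFormatError("cannot blank-correct: no blank wells")
    blank_mean = plate.values[blanks].mean(axis=0)          # (time, channel)
    resid = plate.values[blanks] - blank_mean
    blank_sd = {ch: float(resid[:, :, k].std(ddof=1))
                if len(blanks) > 1 else 0.0
                for k, ch in enumerate(plate.channels)}
    corrected = np.maximum(plate.values - blank_mean, 0.0)
    return replace(plate, values=corrected, blank_corrected=True,
                   blank_sd=blank_sd,
                   metadata=dict(plate.metadata), wells=list(plate.wells),
                   channels=list(plate.channels))


class CalibrationResult(NamedTuple):
    """Fluorescence-to-density calibration with a quality diagnostic."""

    ratio: float        # OD per fluorescence unit
    cv: float           # coefficient of variation of pointwise ratios
    n_points: int


def calibrate_fluorescence(plate: PlateTimeSeries, strain: str,
                           channel: str | None = None) -> CalibrationResult:
    """OD-per-fluorescence ratio from the strain's pure-culture wells.

    Pools all pure wells and time points where both readings clear the
    detection floor (3 x blank standard deviation) and estimates the
    ratio as total OD over total fluorescence — a signal-weighted mean
    of the pointwise ratios, robust to read noise in the denominator at
    low signal. The coefficient of variation of the pointwise ratios is
    reported as a calibration-quality diagnostic. Requires a
    blank-corrected plate.
    """
    if not plate.blank_corrected:
        raise ValueError("calibrate on a blank-corrected plate")
    channel = channel or plate.strain_channels.get(strain)
    if channel is None:
        raise PlateFormatError(f"no channel mapped for strain {strain!r}")
    wells = plate.select_wells(strain=strain, composition="pure")
    if not wells:
        raise PlateFormatError(f"no pure-culture wells for {strain!r}")
    idx = [plate.well_index(w) for w in wells]
    od = plate.values[idx, :, plate.channel_index("OD600")]
    fl = plate.values[idx, :, plate.channel_index(channel)]
    sd = plate.blank_sd or {}
    floor_od = DETECTION_SD * sd.get("OD600", 0.0)
    floor_fl = DETECTION_SD * sd.get(channel, 0.0)
    ok = (od > floor_od) & (fl > floor_fl) & (fl > 0)
    if not ok.any():
        raise PlateFormatError(
            f"all {strain!r} pure-culture readings below detection floor")
    ratio = float(od[ok].sum() / fl[ok].sum())
    pointwise = od[ok] / fl[ok]
    cv = float(pointwise.std(ddof=1) / pointwise.mean()) \
        if pointwise.size > 1 else 0.0
    return CalibrationResult(ratio=ratio, cv=cv, n_points=int(ok.sum()))


def estimated_od(plate: PlateTimeSeries, strain: str,
                 ratio: float | None = None,
                 wells: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-well eOD series: fluorescence x calibration ratio.

    In pure culture eOD tracks OD600 to within the calibration CV; in
    mixed culture it isolates the strain's share of the biomass.
    Returns a DataFrame indexed by well with one column per time point.
    """
    if ratio is None:
        ratio = calibrate_fluorescence(plate, strain).ratio
    channel = plate.strain_channels.get(strain)
    if channel is None:
        raise PlateFormatError(f"no channel mapped for strain {strain!r}")
    if wells is None:
        wells = plate.select_wells(strain=strain)
    idx = [plate.well_index(w) for w in wells]
    eod = plate.values[idx, :, plate.channel_index(channel)] * ratio
    return pd.DataFrame(eod, index=list(wells), columns=plate.times)


# ---------------------------------------------------------------------------
# IC90 estimation
# ---------------------------------------------------------------------------

@dataclass
class Ic90Estimate:
    """Replicate-wise IC90s with a Student-t 95% confidence interval."""

    strain: str
    composition: str
    replicate_ic90: np.ndarray      # NaN where the curve never reached 0.10
    mean: float
    ci95: float                     # half-width; NaN when n < 2
    n: int
    density_at_ic90: float          # endpoint density interpolated at IC90
    metric: str                     # "OD600" or "eOD"

    @property
    def values(self) -> np.ndarray:
        return self.replicate_ic90[np.isfinite(self.replicate_ic90)]


def _t_ci(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, float("nan")
    half = float(stats.t.ppf(0.975, n - 1) * np.std(values, ddof=1)
                 / math.sqrt(n))
    return mean, half


def empirical_ic90(plate: PlateTimeSeries, strain: str,
                   composition: str = "pure", metric: str = "auto",
                   at_time: float = ENDPOINT_H) -> Ic90Estimate:
    """Replicate-wise IC90 of one strain in one culture composition.

    Per replicate, the endpoint reading (grid point nearest ``at_time``)
    is normalised to that replicate's zero-drug well and the 0.10
    crossing interpolated linearly. Pure cultures default to OD600;
    mixed cultures to eOD via the strain's pure-culture calibration.
    Replicates whose curve never reaches 0.10 contribute NaN.
    """
    from .dose_response import DoseResponse, ic90 as _interp_ic90

    if not plate.blank_corrected:
        raise ValueError("empirical_ic90 needs a blank-corrected plate")
    if metric == "auto":
        metric = "OD600" if composition.startswith("pure") else "eOD"
    wells = plate.select_wells(strain=strain, composition=composition)
    if not wells:
        raise PlateFormatError(
            f"no wells for strain={strain!r} composition={composition!r}")

    if metric == "eOD":
        ratio = calibrate_fluorescence(plate, strain).ratio
        endpoint_all = estimated_od(plate, strain, ratio, wells=wells) \
            .iloc[:, plate.endpoint_index(at_time)]
    else:
        k = plate.channel_index("OD600")
        ti = plate.endpoint_index(at_time)
        endpoint_all = pd.Series(
            [plate.values[plate.well_index(w), ti, k] for w in wells],
            index=wells)

    replicates = sorted({plate.metadata[w].replicate for w in wells})
    per_rep, dens = [], []
    for rep in replicates:
        rep_wells = [w for w in wells if plate.metadata[w].replicate == rep]
        conc = np.array([plate.metadata[w].concentration for w in rep_wells])
        order = np.argsort(conc)
        conc = conc[order]
        vals = endpoint_all[rep_wells].to_numpy()[order]
        if conc[0] != 0.0:
            raise PlateFormatError(
                f"replicate {rep} has no zero-drug well for {strain!r}")
        if vals[0] <= 0:
            per_rep.append(np.nan)
            dens.append(np.nan)
            continue
        dr = DoseResponse(concentrations=conc, endpoint_density=vals,
                          normalized=vals / vals[0], focal=strain)
        est = _interp_ic90(dr)
        per_rep.append(np.nan if est is None else est)
        dens.append(np.nan if est is None else dr.density_at(est))

    per_rep = np.array(per_rep, dtype=float)
    finite = per_rep[np.isfinite(per_rep)]
    if finite.size == 0:
        mean, half = float("nan"), float("nan")
    else:
        mean, half = _t_ci(finite)
    dens = np.array(dens, dtype=float)
    dens_mean = float(np.nanmean(dens)) if np.isfinite(dens).any() \
        else float("nan")
    return Ic90Estimate(strain=strain, composition=composition,
                        replicate_ic90=per_rep, mean=mean, ci95=half,
                        n=int(finite.size), density_at_ic90=dens_mean,
                        metric=metric)


# ---------------------------------------------------------------------------
# Exact Wilcoxon-Mann-Whitney
# ---------------------------------------------------------------------------

class MannWhitneyResult(NamedTuple):
    ranksum: float
    pvalue: float
    n1: int
    n2: int
    exact: bool


def _exact_ranksum_dist(doubled: np.ndarray, n1: int):
    """Null distribution of the doubled rank sum of the first sample.

    Dynamic programme over subsets of size ``n1`` of the pooled doubled
    mid-ranks (doubling makes tied mid-ranks integral). Returns
    (support offset implicit) an array p where p[s] = P(2*ranksum = s).
    """
    total = int(doubled.sum())
    counts = np.zeros((n1 + 1, total + 1))
    counts[0, 0] = 1.0
    for w in doubled:
        w = int(w)
        for k in range(n1, 0, -1):
            counts[k, w:] += counts[k - 1, :total + 1 - w]
    dist = counts[n1]
    return dist / dist.sum()


def exact_mann_whitney(x: Sequence[float], y: Sequence[float],
                       method: str = "doubled",
                       exact_limit: int = 20) -> MannWhitneyResult:
    """Rank sum of ``x`` and a two-sided p under the exact null.

    Ties carry mid-ranks. For pooled sizes up to ``exact_limit`` the
    permutation null over all C(n+m, n) assignments is enumerated
    exactly (a subset-sum dynamic programme over the observed pooled
    values); larger samples fall back to the tie-corrected normal
    approximation. ``method="doubled"`` doubles the smaller one-sided
    tail (capped at 1); ``method="tail-sum"`` sums the probability of
    every rank sum at least as far from the null mean as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    ranksum = float(ranks[:n1].sum())

    if n1 + n2 <= exact_limit:
        doubled = np.rint(2.0 * ranks).astype(int)
        dist = _exact_ranksum_dist(doubled, n1)
        s_obs = int(round(2.0 * ranksum))
        p_le = float(dist[:s_obs + 1].sum())
        p_ge = float(dist[s_obs:].sum())
        if method == "doubled":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif method == "tail-sum":
            mu = float(np.dot(np.arange(dist.size), dist))
            dev = abs(s_obs - mu)
            support = np.arange(dist.size)
            p = float(dist[np.abs(support - mu) >= dev - 1e-9].sum())
        else:
            raise ValueError(f"unknown method {method!r}")
        return MannWhitneyResult(ranksum, min(p, 1.0), n1, n2, True)

    # tie-corrected normal approximation for larger samples
    mu = n1 * (n1 + n2 + 1) / 2.0
    tie_counts = np.unique(pooled, return_counts=True)[1]
    n = n1 + n2
    var = (n1 * n2 / 12.0) * (n + 1 - (tie_counts ** 3 - tie_counts).sum()
                              / (n * (n - 1)))
    if var == 0:
        return MannWhitneyResult(ranksum, 1.0, n1, n2, False)
    z = (ranksum - mu) / math.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return MannWhitneyResult(ranksum, p, n1, n2, False)


# ---------------------------------------------------------------------------
# Relative drug content
# ---------------------------------------------------------------------------

def relative_drug_content(ic90_pure: Ic90Estimate | float,
                          ic90_mixed: Ic90Estimate | float,
                          density_pure: float | None = None,
                          density_mixed: float | None = None) -> float:
    """Percent change of per-cell drug content, mixed relative to pure.

    Content per condition is the culture density at the IC90 divided by
    the IC90 concentration. Negative means less drug per cell in mixed
    culture.
    """
    def unpack(est, density):
        if isinstance(est, Ic90Estimate):
            conc, dens = est.mean, est.density_at_ic90
        else:
            conc, dens = float(est), None
        if density is not None:
            dens = float(density)
        if dens is None or not np.isfinite(dens) or dens <= 0:
            raise ValueError("density at IC90 unavailable or non-positive")
        if not np.isfinite(conc) or conc <= 0:
            raise ValueError("IC90 unavailable or non-positive")
        return dens / conc

    content_pure = unpack(ic90_pure, density_pure)
    content_mixed = unpack(ic90_mixed, density_mixed)
    return 100.0 * (content_mixed - content_pure) / content_pure
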