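"""Stabilometric index computation from raw center-of-pressure recordings.

A force platform records the planar trajectory of the center of pressure
(CoP) while a subject stands still: a medio-lateral (ML) and an
antero-posterior (AP) displacement series, in millimetres, sampled
uniformly (device constant 50 Hz, one minute per eye condition).  From
one recording this module computes the classical posturographic index
set — time-domain distance, area and hybrid measures plus
frequency-domain spectral measures — 39 named indexes per eye condition,
78 per subject across the eyes-open (OE) and eyes-closed (CE) conditions.

The roster lives in :data:`METRIC_REGISTRY` so it can be amended without
touching the computation code.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "CoPRecording",
    "SwaySeries",
    "SpectralConfig",
    "METRIC_REGISTRY",
    "METRIC_UNITS",
    "preprocess",
    "resample",
    "distance_measures",
    "area_measures",
    "hybrid_measures",
    "frequency_measures",
    "compute_metrics",
    "compute_all_metrics",
    "read_recording_csv",
    "write_recording_csv",
    "metrics_to_tidy",
    "metrics_to_wide",
]

DEVICE_SAMPLE_RATE = 50.0  # Hz
NOMINAL_DURATION = 60.0  # s per eye condition
DISPLACEMENT_RESOLUTION = 0.01  # mm

# 95% confidence constants of the classical sway-area formulas:
# z for the one-dimensional radial bound, large-sample F(0.05; 2, n-2).
Z95 = 1.645
F95_LARGE_N = 3.00

CONDITIONS = ("OE", "CE")


class InvalidRecordingError(ValueError):
    """Raised for recordings that cannot be analysed (too short, bad grid)."""


class ResamplingRequiredError(ValueError):
    """Raised when timestamps are too irregular for direct analysis."""


@dataclass(frozen=True)
class SpectralConfig:
    """Welch PSD estimation settings for the frequency-domain measures.

    Defaults: Hann window, 10 s segments with 50% overlap, linear detrend
    per segment, analysis band 0.15–5 Hz (the conventional posturography
    band, excluding slow drift below 0.15 Hz and noise above 5 Hz).
    """

    band_low: float = 0.15
    band_high: float = 5.0
    segment_seconds: float = 10.0
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "linear"


@dataclass(frozen=True)
class CoPRecording:
    """One subject x one eye condition of raw CoP displacement data."""

    subject_id: str
    condition: str  # "OE" or "CE"
    sample_rate: float
    t: np.ndarray  # s, uniform
    ml: np.ndarray  # mm
    ap: np.ndarray  # mm

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ml = np.asarray(self.ml, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "ap", ap)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not (len(t) == len(ml) == len(ap)):
            raise InvalidRecordingError("t, ml and ap must have equal length")
        if len(t) < 2:
            raise InvalidRecordingError("a recording needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidRecordingError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sample_rate)) > 1e-9:
            raise ResamplingRequiredError(
                "timestamps deviate from the uniform grid; resample() first"
            )

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Record span (n-1)/fs in seconds."""
        return (self.n - 1) / self.sample_rate

    def is_short(self) -> bool:
        return self.duration < NOMINAL_DURATION - 1.0 / self.sample_rate


@dataclass(frozen=True)
class SwaySeries:
    """Zero-meaned sway series ready for index computation.

    AP/ML are the mean-removed displacement series (mm); RD is the
    resultant distance from the mean CoP position, RD[i] =
    sqrt(AP[i]^2 + ML[i]^2).  T is the record span in seconds.
    """

    AP: np.ndarray
    ML: np.ndarray
    RD: np.ndarray
    T: float
    n: int
    sample_rate: float


def preprocess(rec: CoPRecording) -> SwaySeries:
    """Zero-center a recording and derive the resultant-distance series."""
    ap = rec.ap - rec.ap.mean()
    ml = rec.ml - rec.ml.mean()
    rd = np.hypot(ap, ml)
    return SwaySeries(AP=ap, ML=ml, RD=rd, T=rec.duration, n=rec.n,
                      sample_rate=rec.sample_rate)


def resample(t: np.ndarray, x: np.ndarray, target_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate an irregular series onto a uniform grid.

    The grid runs from t[0] to t[-1] at ``target_rate``; returns
    (t_uniform, x_uniform).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing (no duplicates)")
    n_out = int(np.floor((t[-1] - t[0]) * target_rate + 1e-9)) + 1
    t_out = t[0] + np.arange(n_out) / target_rate
    return t_out, np.interp(t_out, t, x)


# ---------------------------------------------------------------------------
# Time-domain distance measures
# ---------------------------------------------------------------------------

def _planar_range(ap: np.ndarray, ml: np.ndarray) -> float:
    """Maximum pairwise planar distance, via the convex hull (O(n log n))."""
    pts = np.column_stack([ap, ml])
    pts = np.unique(pts, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) == 2:
        return float(np.hypot(*(pts[1] - pts[0])))
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear points
        hull = pts
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def distance_measures(s: SwaySeries) -> dict[str, float]:
    """Mean/RMS distance, range, total excursion and mean velocity.

    Per axis d in {AP, ML} and for the planar trajectory:
    MDIST = mean(RD), MDISTd = mean(|d|); RDIST = rms(RD), RDISTd =
    rms(d); RANGEd = max(d) - min(d), planar RANGE = max pairwise
    distance; TOTEX = total path length; MVEL = TOTEX / T.
    """
    ap, ml, rd, T = s.AP, s.ML, s.RD, s.T
    totex_ap = float(np.abs(np.diff(ap)).sum())
    totex_ml = float(np.abs(np.diff(ml)).sum())
    totex = float(np.hypot(np.diff(ap), np.diff(ml)).sum())
    return {
        "MDIST": float(rd.mean()),
        "MDISTAP": float(np.abs(ap).mean()),
        "MDISTML": float(np.abs(ml).mean()),
        "RDIST": float(np.sqrt(np.mean(rd ** 2))),
        "RDISTAP": float(np.sqrt(np.mean(ap ** 2))),
        "RDISTML": float(np.sqrt(np.mean(ml ** 2))),
        "RANGE": _planar_range(ap, ml),
        "RANGEAP": float(ap.max() - ap.min()),
        "RANGEML": float(ml.max() - ml.min()),
        "TOTEX": totex,
        "TOTEXAP": totex_ap,
        "TOTEXML": totex_ml,
        "MVEL": totex / T,
        "MVELAP": totex_ap / T,
        "MVELML": totex_ml / T,
    }


# ---------------------------------------------------------------------------
# Area measures
# ---------------------------------------------------------------------------

def _sway_covariances(s: SwaySeries) -> tuple[float, float, float]:
    n = s.n
    s_ap2 = float(np.sum(s.AP ** 2) / (n - 1))
    s_ml2 = float(np.sum(s.ML ** 2) / (n - 1))
    s_apml = float(np.sum(s.AP * s.ML) / (n - 1))
    return s_ap2, s_ml2, s_apml


def area_measures(s: SwaySeries, *, exact_quantiles: bool = False) -> dict[str, float]:
    """95% confidence circle/ellipse areas and sway area per unit time.

    AREA_CC = pi * (MDIST + 1.645 * SD(RD))^2
    AREA_CE = 2 * pi * F * sqrt(s_AP^2 * s_ML^2 - s_APML^2), F = 3.00
    AREA_SW = (1 / 2T) * sum |AP[i+1] ML[i] - AP[i] ML[i+1]|

    ``exact_quantiles`` replaces the fixed large-sample constants with
    the exact F(0.05; 2, n-2) quantile.
    """
    if s.n < 3:
        raise InvalidRecordingError("area measures need at least 3 samples")
    rd = s.RD
    mdist = float(rd.mean())
    s_rd = float(rd.std(ddof=1))
    if exact_quantiles:
        from scipy.stats import f as f_dist
        F = float(f_dist.ppf(0.95, 2, s.n - 2))
    else:
        F = F95_LARGE_N
    s_ap2, s_ml2, s_apml = _sway_covariances(s)
    disc = max(s_ap2 * s_ml2 - s_apml ** 2, 0.0)
    cross = np.abs(s.AP[1:] * s.ML[:-1] - s.AP[:-1] * s.ML[1:])
    return {
        "AREA_CC": math.pi * (mdist + Z95 * s_rd) ** 2,
        "AREA_CE": 2.0 * math.pi * F * math.sqrt(disc),
        "AREA_SW": float(cross.sum()) / (2.0 * s.T),
    }


# ---------------------------------------------------------------------------
# Hybrid measures (frequency from time-domain quantities)
# ---------------------------------------------------------------------------

def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0.0:
        if num != 0.0:
            warnings.warn(f"{name}: zero denominator, reporting 0 by convention")
        return 0.0
    return num / den


def hybrid_measures(s: SwaySeries, dm: dict[str, float] | None = None,
                    am: dict[str, float] | None = None) -> dict[str, float]:
    """Mean rotational frequency and fractal-dimension measures.

    MFREQ = MVEL / (2 pi MDIST) — the rotation rate of a circle whose
    radius is the mean distance, swept at the mean velocity.
    MFREQd = MVELd / (4 sqrt(2) MDISTd), the axis analogue.
    FD_* = ln(n) / ln(n d / TOTEX) with d the planar range (FD_PD), the
    confidence-circle diameter (FD_CC) or the equivalent confidence-
    ellipse diameter (FD_CE).  Ratio measures are 0 on degenerate input.
    """
    dm = dm if dm is not None else distance_measures(s)
    am = am if am is not None else area_measures(s)
    n = s.n
    out = {
        "MFREQ": _safe_ratio(dm["MVEL"], 2.0 * math.pi * dm["MDIST"], "MFREQ"),
        "MFREQAP": _safe_ratio(dm["MVELAP"], 4.0 * math.sqrt(2.0) * dm["MDISTAP"], "MFREQAP"),
        "MFREQML": _safe_ratio(dm["MVELML"], 4.0 * math.sqrt(2.0) * dm["MDISTML"], "MFREQML"),
    }
    totex = dm["TOTEX"]
    d_pd = dm["RANGE"]
    d_cc = 2.0 * (dm["MDIST"] + Z95 * float(s.RD.std(ddof=1)))
    d_ce = math.sqrt(4.0 * am["AREA_CE"] / math.pi)
    for name, d in (("FD_PD", d_pd), ("FD_CC", d_cc), ("FD_CE", d_ce)):
        if totex == 0.0 or d == 0.0 or n * d == totex:
            out[name] = 0.0
        else:
            denom = math.log(n * d / totex)
            out[name] = 0.0 if denom == 0.0 else math.log(n) / denom
    return out


# ---------------------------------------------------------------------------
# Frequency-domain measures
# ---------------------------------------------------------------------------

def _psd(x: np.ndarray, fs: float, cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(cfg.segment_seconds * fs))
    if nperseg > len(x):
        warnings.warn("record shorter than one PSD segment; using a single segment")
        nperseg = len(x)
    noverlap = int(round(cfg.overlap * nperseg))
    return sps.welch(x, fs=fs, window=cfg.window, nperseg=nperseg,
                     noverlap=noverlap, detrend=cfg.detrend)


def _spectral_measures(x: np.ndarray, fs: float, cfg: SpectralConfig) -> dict[str, float]:
    f, g = _psd(x, fs, cfg)
    band = (f >= cfg.band_low) & (f <= cfg.band_high)
    f, g = f[band], g[band]
    df = f[1] - f[0] if len(f) > 1 else 1.0 / cfg.segment_seconds
    mu0 = float(np.sum(g) * df)
    if mu0 <= 0.0:
        return {"POWER": 0.0, "POWER50": 0.0, "POWER95": 0.0, "CFREQ": 0.0, "FREQD": 0.0}
    mu1 = float(np.sum(f * g) * df)
    mu2 = float(np.sum(f ** 2 * g) * df)
    cum = np.cumsum(g) * df
    p50 = float(f[np.searchsorted(cum, 0.50 * mu0)])
    p95 = float(f[np.searchsorted(cum, 0.95 * mu0)])
    cfreq = math.sqrt(mu2 / mu0)
    freqd = math.sqrt(max(1.0 - mu1 ** 2 / (mu0 * mu2), 0.0)) if mu2 > 0 else 0.0
    return {"POWER": mu0, "POWER50": p50, "POWER95": p95, "CFREQ": cfreq, "FREQD": freqd}


def frequency_measures(s: SwaySeries, cfg: SpectralConfig | None = None) -> dict[str, float]:
    """Spectral-moment measures of the AP, ML and RD series.

    The one-sided Welch power spectral density G(f) is integrated over
    the analysis band; spectral moments mu_k = sum f^k G(f) df give
    POWER (total power, mu_0), POWER50/POWER95 (frequencies below which
    50%/95% of the band power lies), CFREQ (centroidal frequency,
    sqrt(mu_2/mu_0)) and FREQD (frequency dispersion,
    sqrt(1 - mu_1^2/(mu_0 mu_2)); 0 for a pure line, 1 for maximally
    spread power).
    """
    cfg = cfg or SpectralConfig()
    if cfg.band_high >= s.sample_rate / 2.0:
        raise ValueError("band upper edge must be below the Nyquist frequency")
    out: dict[str, float] = {}
    for label, x in (("AP", s.AP), ("ML", s.ML), ("RD", s.RD)):
        for k, v in _spectral_measures(x, s.sample_rate, cfg).items():
            out[f"{k}{label}"] = v
    return out


# ---------------------------------------------------------------------------
# Registry and assembly
# ---------------------------------------------------------------------------

def _registry() -> tuple[tuple[str, str], ...]:
    dist = [
        ("MDIST", "mm"), ("MDISTAP", "mm"), ("MDISTML", "mm"),
        ("RDIST", "mm"), ("RDISTAP", "mm"), ("RDISTML", "mm"),
        ("RANGE", "mm"), ("RANGEAP", "mm"), ("RANGEML", "mm"),
        ("TOTEX", "mm"), ("TOTEXAP", "mm"), ("TOTEXML", "mm"),
        ("MVEL", "mm/s"), ("MVELAP", "mm/s"), ("MVELML", "mm/s"),
    ]
    area = [("AREA_CC", "mm^2"), ("AREA_CE", "mm^2"), ("AREA_SW", "mm^2/s")]
    hybrid = [("MFREQ", "Hz"), ("MFREQAP", "Hz"), ("MFREQML", "Hz"),
              ("FD_PD", ""), ("FD_CC", ""), ("FD_CE", "")]
    spectral = [(f"{base}{axis}", unit)
                for axis in ("AP", "ML", "RD")
                for base, unit in (("POWER", "mm^2"), ("POWER50", "Hz"),
                                   ("POWER95", "Hz"), ("CFREQ", "Hz"), ("FREQD", ""))]
    return tuple(dist + area + hybrid + spectral)


#: The 39 per-condition index names with units; amend here to change the roster.
METRIC_REGISTRY: tuple[tuple[str, str], ...] = _registry()
METRIC_NAMES: tuple[str, ...] = tuple(name for name, _ in METRIC_REGISTRY)
METRIC_UNITS: dict[str, str] = dict(METRIC_REGISTRY)
assert len(METRIC_NAMES) == 39


def compute_metrics(rec: CoPRecording, cfg: SpectralConfig | None = None) -> dict[str, float]:
    """All 39 per-condition indexes of one recording (no condition suffix)."""
    s = preprocess(rec)
    dm = distance_measures(s)
    am = area_measures(s)
    out: dict[str, float] = {}
    out.update(dm)
    out.update(am)
    out.update(hybrid_measures(s, dm, am))
    out.update(frequency_measures(s, cfg))
    return {name: out[name] for name in METRIC_NAMES}


def compute_all_metrics(rec_oe: CoPRecording | None,
                        rec_ce: CoPRecording | None = None,
                        cfg: SpectralConfig | None = None) -> dict[str, float]:
    """The 78-entry subject vector, names suffixed OE/CE.

    A missing condition yields NaN entries for its 39 indexes so the
    vector shape is stable.
    """
    if rec_oe is None and rec_ce is None:
        raise ValueError("at least one condition must be provided")
    subjects = {r.subject_id for r in (rec_oe, rec_ce) if r is not None}
    if len(subjects) > 1:
        raise ValueError(f"recordings belong to different subjects: {sorted(subjects)}")
    out: dict[str, float] = {}
    for cond, rec in (("OE", rec_oe), ("CE", rec_ce)):
        if rec is None:
            out.update({f"{name}{cond}": float("nan") for name in METRIC_NAMES})
        else:
            if rec.condition != cond:
                raise ValueError(f"expected condition {cond}, got {rec.condition}")
            out.update({f"{k}{cond}": v for k, v in compute_metrics(rec, cfg).items()})
    return out


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

def write_recording_csv(rec: CoPRecording, path: str | Path) -> None:
    """One recording per file: '# subject,condition,rate' header then
    time_s, ml_mm, ap_mm columns."""
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id} condition={rec.condition} "
                 f"sample_rate={rec.sample_rate}\n")
        fh.write("time_s,ml_mm,ap_mm\n")
        for t, ml, ap in zip(rec.t, rec.ml, rec.ap):
            fh.write(f"{t:.6f},{ml:.4f},{ap:.4f}\n")


def read_recording_csv(path: str | Path) -> CoPRecording:
    path = Path(path)
    subject_id, condition, rate = path.stem, "OE", DEVICE_SAMPLE_RATE
    text = path.read_text()
    if text.startswith("#"):
        header, _, text = text.partition("\n")
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        subject_id = meta.get("subject_id", subject_id)
        condition = meta.get("condition", condition)
        rate = float(meta.get("sample_rate", rate))
    else:
        # filename pattern <subject>_<OE|CE>
        if "_" in path.stem:
            subject_id, cond = path.stem.rsplit("_", 1)
            if cond in CONDITIONS:
                condition = cond
    df = pd.read_csv(io.StringIO(text))
    return CoPRecording(subject_id=subject_id, condition=condition, sample_rate=rate,
                        t=df["time_s"].to_numpy(), ml=df["ml_mm"].to_numpy(),
                        ap=df["ap_mm"].to_numpy())


def metrics_to_tidy(subject_id: str, metrics: dict[str, float]) -> pd.DataFrame:
    rows = []
    for name, value in metrics.items():
        base = name[:-2] if name.endswith(("OE", "CE")) else name
        rows.append({"subject_id": subject_id, "metric": name,
                     "value": value, "units": METRIC_UNITS.get(base, "")})
    return pd.DataFrame(rows)


def metrics_to_wide(per_subject: dict[str, dict[str, float]]) -> pd.DataFrame:
    """subject_id-indexed wide table, one column per suffixed index."""
    df = pd.DataFrame.from_dict(per_subject, orient="index")
    df.index.name = "subject_id"
    return df
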