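"""Plate-reader measurement pipeline and replicate statistics.

The corrections follow the fixed three-step arithmetic: (1) subtract the
media-blank mean from raw OD and FL, (2) divide corrected FL by corrected OD
per well, (3) subtract the mean FL/OD of the autofluorescent blank cells.
Negative corrected values are retained (not clipped) so replicate statistics
stay unbiased; wells whose corrected OD falls at or below ``od_floor`` are
flagged and excluded from FL/OD.

Statistics: fold activation (ratio of group means), Pearson copy-number
correlation on replicate-level points, Welch two-sample t-test, and
one/two-way ANOVA with post-hoc Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.optimize import isotonic_regression
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ParameterError, PlateError, UndefinedStatisticError

__all__ = [
    "ROLES",
    "CHANNELS",
    "PlateDataset",
    "CorrectedMeasurements",
    "StandardCurve",
    "correct_plate",
    "fold_activation",
    "build_standard_curve",
    "map_inducer_to_activity",
    "copy_correlation",
    "welch_ttest",
    "anova_tukey",
    "read_plate_csv",
]

ROLES = ("media_blank", "blank_cells", "sample")
#: Fluorescence channels: GFP read at 485/520 nm, RFP at 560/630 nm.
CHANNELS = ("GFP", "RFP")
OD_FLOOR = 0.01


@dataclass
class PlateDataset:
    """Raw wells-by-channels table with role/condition/replicate annotations.

    ``frame`` must carry at least ``well``, ``role``, ``replicate``,
    ``OD600`` and one ``FL_<channel>`` column; any other columns are treated
    as condition labels and carried through the pipeline untouched.
    """

    frame: pd.DataFrame
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        df = self.frame
        required = {"well", "role", "replicate", "OD600"}
        missing = required - set(df.columns)
        if missing:
            raise PlateError(f"plate table missing columns: {sorted(missing)}")
        self.channels = tuple(
            ch for ch in self.channels if f"FL_{ch}" in df.columns
        )
        if not self.channels:
            raise PlateError("plate table has no FL_<channel> column")
        bad_roles = set(df["role"]) - set(ROLES)
        if bad_roles:
            raise PlateError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        for role in ("media_blank", "blank_cells"):
            if not (df["role"] == role).any():
                raise PlateError(f"plate must contain at least one {role} well")
        value_cols = ["OD600"] + [f"FL_{ch}" for ch in self.channels]
        if not np.all(np.isfinite(df[value_cols].to_numpy(dtype=float))):
            raise PlateError("raw OD/FL values must all be finite")

    @property
    def samples(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "sample"]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> PlateDataset:
    """Load a tidy plate CSV (``well,role,...,replicate,OD600,FL_GFP[,FL_RFP]``)."""
    return PlateDataset(frame=pd.read_csv(path))


@dataclass
class CorrectedMeasurements:
    """Per-well corrected values.

    ``frame`` extends the raw table with ``od_corr``, and per channel
    ``fl_corr_<ch>``, ``flod_<ch>`` (corrected FL / corrected OD) and
    ``flod_sub_<ch>`` (autofluorescence-subtracted).  ``excluded`` flags
    wells with corrected OD at or below the floor; their FL/OD is NaN.
    """

    frame: pd.DataFrame
    channels: tuple[str, ...]
    od_floor: float
    autofluorescence: dict[str, float] = field(default_factory=dict)

    def samples(self) -> pd.DataFrame:
        df = self.frame
        return df[(df["role"] == "sample") & ~df["excluded"]]

    def flod(self, channel: str = "GFP", subtracted: bool = True) -> pd.Series:
        col = f"flod_sub_{channel}" if subtracted else f"flod_{channel}"
        return self.samples()[col]


def correct_plate(plate: PlateDataset, od_floor: float = OD_FLOOR) -> CorrectedMeasurements:
    """Apply the three-step blank/autofluorescence correction.

    Order is fixed: media-blank subtraction, then the FL/OD ratio, then
    subtraction of the blank-cell FL/OD mean.
    """
    df = plate.frame.copy()
    blanks = df[df["role"] == "media_blank"]
    df["od_corr"] = df["OD600"] - blanks["OD600"].mean()
    for ch in plate.channels:
        df[f"fl_corr_{ch}"] = df[f"FL_{ch}"] - blanks[f"FL_{ch}"].mean()

    df["excluded"] = df["od_corr"] <= od_floor
    n_flagged = int(df.loc[df["role"] == "sample", "excluded"].sum())
    if n_flagged:
        warnings.warn(
            f"{n_flagged} sample well(s) with corrected OD <= {od_floor} "
            "flagged and excluded from FL/OD",
            stacklevel=2,
        )

    autofl: dict[str, float] = {}
    for ch in plate.channels:
        ratio = np.where(df["excluded"], np.nan, df[f"fl_corr_{ch}"] / df["od_corr"])
        df[f"flod_{ch}"] = ratio
        cells = df[(df["role"] == "blank_cells") & ~df["excluded"]]
        if cells.empty:
            raise PlateError("all blank_cells wells excluded; cannot estimate autofluorescence")
        autofl[ch] = float(cells[f"flod_{ch}"].mean())
        df[f"flod_sub_{ch}"] = df[f"flod_{ch}"] - autofl[ch]
    return CorrectedMeasurements(frame=df, channels=plate.channels,
                                 od_floor=od_floor, autofluorescence=autofl)


def fold_activation(on: Sequence[float], off: Sequence[float]) -> float:
    """Ratio of replicate means, activator present over absent."""
    on = np.asarray(list(on), dtype=float)
    off = np.asarray(list(off), dtype=float)
    if on.size == 0 or off.size == 0:
        raise UndefinedStatisticError("fold activation needs non-empty on and off groups")
    if off.mean() <= 0:
        raise UndefinedStatisticError(
            f"fold activation undefined: mean(off) = {off.mean():g} <= 0"
        )
    return float(on.mean() / off.mean())


@dataclass(frozen=True)
class StandardCurve:
    """Monotone inducer-concentration -> FL/OD mapping of an inducible
    reporter control, used to express inducer doses as relative promoter
    activity (normalized so the highest-induction knot maps to 1)."""

    concentrations: np.ndarray
    values: np.ndarray  # isotonic-adjusted knot means (FL/OD units)

    def __post_init__(self):
        if np.any(np.diff(self.concentrations) <= 0):
            raise ParameterError("concentrations", "knot concentrations must be strictly increasing")
        if np.any(np.diff(self.values) < 0):
            raise ParameterError("values", "knot values must be monotone non-decreasing")

    @property
    def max_value(self) -> float:
        return float(self.values[-1])

    def query(self, concentration: float) -> float:
        """Interpolated (unnormalized) FL/OD at a concentration within range."""
        c = float(concentration)
        lo, hi = self.concentrations[0], self.concentrations[-1]
        if c < min(0.0, lo) or c > hi:
            raise ParameterError(
                "concentration", f"{c:g} outside the calibrated range [{lo:g}, {hi:g}]"
            )
        if c < lo:  # below lowest knot but >= 0: clamp to basal
            return float(self.values[0])
        return float(np.interp(c, self.concentrations, self.values))

    def inverse(self, value: float) -> float:
        """Concentration whose curve value equals ``value`` (lowest branch)."""
        v = float(value)
        if v < self.values[0] or v > self.values[-1]:
            raise ParameterError("value", f"{v:g} outside the curve's value range")
        return float(np.interp(v, self.values, self.concentrations))


def build_standard_curve(
    control_plate: PlateDataset | CorrectedMeasurements,
    channel: str = "GFP",
    inducer_col: str = "inducer",
    tolerance: float = 0.0,
) -> StandardCurve:
    """Fit a monotone piecewise-linear curve through the replicate means of
    an inducible reporter control.

    Non-monotone knot means (beyond ``tolerance`` relative) trigger isotonic
    adjustment with a warning; the curve then passes through the adjusted
    means but still returns knot values exactly at knot concentrations.
    """
    corrected = control_plate if isinstance(control_plate, CorrectedMeasurements) \
        else correct_plate(control_plate)
    samples = corrected.samples()
    if inducer_col not in samples.columns:
        raise PlateError(f"control plate has no {inducer_col!r} column")
    means = (
        samples.groupby(inducer_col)[f"flod_sub_{channel}"].mean().sort_index()
    )
    if len(means) < 3:
        raise PlateError(
            f"standard curve needs >= 3 inducer levels, got {len(means)}"
        )
    conc = means.index.to_numpy(dtype=float)
    vals = means.to_numpy(dtype=float)
    drops = -np.minimum(np.diff(vals), 0.0)
    scale = max(abs(vals).max(), np.finfo(float).tiny)
    if np.any(drops > tolerance * scale):
        warnings.warn(
            "non-monotone standard-curve means; applying isotonic adjustment",
            stacklevel=2,
        )
        vals = isotonic_regression(vals).x
    return StandardCurve(concentrations=conc, values=np.asarray(vals, dtype=float))


def map_inducer_to_activity(curve: StandardCurve, concentration: float) -> float:
    """Relative promoter activity of an inducer dose: the curve value at the
    dose divided by the highest-induction knot value (== 1.0 at the top knot)."""
    if curve.max_value <= 0:
        raise UndefinedStatisticError("standard curve has non-positive maximum; cannot normalize")
    return curve.query(concentration) / curve.max_value


def copy_correlation(table: pd.DataFrame | Iterable[tuple[float, float]],
                     copy_col: str = "copies", value_col: str = "flod") -> dict:
    """Pearson correlation between copy number and FL/OD on replicate-level
    points, with a two-sided t-based p-value and ``df = N - 2``."""
    if isinstance(table, pd.DataFrame):
        x = table[copy_col].to_numpy(dtype=float)
        y = table[value_col].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(table), dtype=float)
        x, y = pairs[:, 0], pairs[:, 1]
    if np.unique(x).size < 3:
        raise UndefinedStatisticError(
            f"copy correlation needs >= 3 distinct copy levels, got {np.unique(x).size}"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance in copy or value column")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "df": int(x.size - 2)}


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-tailed Welch (unequal-variance) t-test.

    Returns the exact Welch-Satterthwaite ``df`` along with the pooled
    ``df_pooled = n_a + n_b - 2`` reporting convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("each group needs >= 2 replicates")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "df_pooled": int(a.size + b.size - 2),
        "p": float(res.pvalue),
    }


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_tukey(
    data: pd.DataFrame,
    value_col: str,
    factors: Sequence[str],
    alpha: float = 0.05,
) -> dict:
    """One- or two-way ANOVA with a post-hoc Tukey HSD test.

    For two factors the model includes both main effects and their
    interaction.  Returns the ANOVA table, a Tukey table of pairwise adjusted
    p-values over the factor-level cells, and star annotations at the
    .05/.01/.001 thresholds.
    """
    if not 1 <= len(factors) <= 2:
        raise ParameterError("factors", "expect 1 or 2 categorical factors")
    df = data.copy()
    cell = df[list(factors)].astype(str).agg(":".join, axis=1)
    counts = cell.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise UndefinedStatisticError(f"cells with < 2 replicates: {small}")

    terms = [f"C({f})" for f in factors]
    if len(factors) == 2:
        terms.append(f"C({factors[0]}):C({factors[1]})")
    formula = f"{value_col} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    anova = anova.rename(columns={"PR(>F)": "p"})
    anova["signif"] = [_stars(p) if np.isfinite(p) else "" for p in anova["p"]]

    tukey = pairwise_tukeyhsd(df[value_col].to_numpy(dtype=float), cell.to_numpy(), alpha=alpha)
    tukey_df = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    tukey_df["p-adj"] = np.asarray(tukey.pvalues, dtype=float)  # unrounded
    tukey_df["signif"] = tukey_df["p-adj"].map(_stars)
    return {"anova": anova, "tukey": tukey_df}
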