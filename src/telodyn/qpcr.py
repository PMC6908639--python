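"""Relative telomere-length quantification from qPCR plate data.

A plate multiplexes a telomere-repeat target (TEL) and a single-copy
reference gene (SCG) and carries, for each target, a serial-dilution
series of a standard DNA (five 3-fold steps spanning 2.22-180 ng, an
81-fold range).  For each target a standard curve

    Ct = slope * log10(quantity_ng) + intercept

is fitted by ordinary least squares to the dilution series; amplification
efficiency is 10^(-1/slope) - 1 (a perfectly doubling reaction has slope
-1/log10(2) = -3.3219 and efficiency 1.0).  Unknown samples are
interpolated on the curve, and the telomere-to-single-copy ratio
T/S = q_TEL / q_SCG is proportional to mean telomere length per sample.
Replicate wells (triplicates by design) are aggregated as the mean Ct
after dropping replicates more than a configurable distance from the
replicate median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateData",
    "StandardCurve",
    "TSRatio",
    "read_plate",
    "aggregate_replicates",
    "fit_standard_curve",
    "quantify",
    "compute_ts",
    "simulate_plate",
    "DEFAULT_STANDARD_QUANTITIES",
]

TARGETS = ("TEL", "SCG")
ROLES = ("standard", "unknown", "reference")

#: The five 3-fold dilution quantities (ng) of the default standard series.
DEFAULT_STANDARD_QUANTITIES = (180.0, 60.0, 20.0, 20.0 / 3.0, 20.0 / 9.0)

#: Slope of a perfectly doubling reaction: -1/log10(2) cycles per decade.
PERFECT_DOUBLING_SLOPE = -1.0 / math.log10(2.0)

#: Default replicate-outlier threshold: drop a replicate whose Ct is more
#: than this many cycles from the replicate median.
DEFAULT_CT_OUTLIER = 0.5


class PlateError(ValueError):
    """Malformed plate data or an unusable standard series."""


@dataclass(frozen=True)
class PlateData:
    """Wells of one plate: well, sample, target, role, ct, quantity_ng."""

    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        w = self.wells
        required = ["well", "sample", "target", "role", "ct", "quantity_ng"]
        missing = [c for c in required if c not in w.columns]
        if missing:
            raise PlateError(f"plate table missing columns: {missing}")
        bad_t = set(w["target"]) - set(TARGETS)
        if bad_t:
            raise PlateError(f"unknown targets: {sorted(bad_t)}")
        bad_r = set(w["role"]) - set(ROLES)
        if bad_r:
            raise PlateError(f"unknown roles: {sorted(bad_r)}")
        std = w[w["role"] == "standard"]
        if (std["quantity_ng"].isna() | (std["quantity_ng"] <= 0)).any():
            raise PlateError("standards must carry a positive quantity_ng")

    def standards(self, target: str) -> pd.DataFrame:
        w = self.wells
        return w[(w["role"] == "standard") & (w["target"] == target)]

    def samples(self) -> list[str]:
        w = self.wells
        return sorted(set(w.loc[w["role"] != "standard", "sample"]))

    def write_csv(self, path) -> None:
        self.wells.to_csv(path, index=False)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear standard curve for one target."""

    target: str
    slope: float
    intercept: float
    r_squared: float
    quantity_range: tuple[float, float]

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct_at(self, quantity_ng: float) -> float:
        return self.slope * math.log10(quantity_ng) + self.intercept


@dataclass(frozen=True)
class TSRatio:
    """Telomere-to-single-copy ratio for one sample."""

    sample: str
    t_quantity: float
    s_quantity: float
    ts: float
    qc_flags: tuple[str, ...] = ()


def read_plate(path) -> PlateData:
    """Read the plate CSV (columns well, sample, target, role, ct,
    quantity_ng; quantity blank for unknowns)."""
    w = pd.read_csv(path, dtype={"well": str, "sample": str})
    w["ct"] = pd.to_numeric(w["ct"], errors="coerce")
    w["quantity_ng"] = pd.to_numeric(w["quantity_ng"], errors="coerce")
    return PlateData(w)


def aggregate_replicates(cts, ct_outlier: float = DEFAULT_CT_OUTLIER):
    """Aggregate replicate Ct values for one (sample, target).

    Replicates more than ``ct_outlier`` cycles from the replicate median
    are dropped; the mean of the survivors is returned together with QC
    flags (``ct_outlier`` if any replicate was dropped,
    ``low_replication`` if fewer than 2 survive).
    """
    cts = np.asarray(cts, dtype=float)
    cts = cts[np.isfinite(cts)]
    if len(cts) == 0:
        raise ValueError("no finite Ct replicates")
    med = np.median(cts)
    keep = np.abs(cts - med) <= ct_outlier
    flags: list[str] = []
    if not keep.all():
        flags.append("ct_outlier")
    survivors = cts[keep]
    if len(survivors) < 2:
        flags.append("low_replication")
    return float(survivors.mean()), tuple(flags)


def fit_standard_curve(plate: PlateData, target: str,
                       ct_outlier: float = DEFAULT_CT_OUTLIER) -> StandardCurve:
    """OLS fit of aggregated standard Cts on log10(quantity)."""
    std = plate.standards(target)
    quantities = sorted(set(std["quantity_ng"]))
    if len(quantities) < 3:
        raise PlateError(
            f"{target}: need >= 3 distinct standard quantities, "
            f"got {len(quantities)}"
        )
    xs, ys = [], []
    for q in quantities:
        cts = std.loc[std["quantity_ng"] == q, "ct"]
        ct, _ = aggregate_replicates(cts, ct_outlier)
        xs.append(math.log10(q))
        ys.append(ct)
    res = stats.linregress(xs, ys)
    if res.slope >= 0:
        raise PlateError(f"{target}: non-negative standard-curve slope")
    return StandardCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        quantity_range=(min(quantities), max(quantities)),
    )


def quantify(curve: StandardCurve, ct: float,
             extrapolation_tol: float = 0.05):
    """Invert the standard curve: quantity = 10^((ct - intercept)/slope).

    Returns ``(quantity_ng, flags)``; quantities outside the standard
    range (with ``extrapolation_tol`` relative slack) are flagged.
    """
    if not np.isfinite(ct):
        raise ValueError("non-finite Ct")
    q = 10.0 ** ((ct - curve.intercept) / curve.slope)
    lo, hi = curve.quantity_range
    flags: tuple[str, ...] = ()
    if q < lo * (1.0 - extrapolation_tol) or q > hi * (1.0 + extrapolation_tol):
        flags = ("extrapolated",)
    return float(q), flags


def compute_ts(plate: PlateData, reference: str | None = None,
               ct_outlier: float = DEFAULT_CT_OUTLIER) -> list[TSRatio]:
    """T/S ratios for every non-standard sample on a plate.

    Fits both standard curves, aggregates replicates per (sample, target),
    interpolates quantities and takes T/S = q_TEL / q_SCG.  If a
    ``reference`` sample is named, all ratios are divided by its ratio
    (so the reference itself reports 1.0); by default ratios are the raw
    standard-DNA-matched quantity ratios.
    """
    curves = {t: fit_standard_curve(plate, t, ct_outlier) for t in TARGETS}
    w = plate.wells
    results: list[TSRatio] = []
    for sample in plate.samples():
        flags: list[str] = []
        quantities: dict[str, float] = {}
        for target in TARGETS:
            sel = w[(w["sample"] == sample) & (w["target"] == target)
                    & (w["role"] != "standard")]
            cts = sel["ct"].to_numpy(dtype=float)
            cts = cts[np.isfinite(cts)]
            if len(cts) == 0:
                flags.append(f"missing_{target.lower()}")
                continue
            ct, agg_flags = aggregate_replicates(cts, ct_outlier)
            flags.extend(f"{target.lower()}_{f}" for f in agg_flags)
            q, q_flags = quantify(curves[target], ct)
            flags.extend(f"{target.lower()}_{f}" for f in q_flags)
            quantities[target] = q
        if set(quantities) != set(TARGETS):
            results.append(TSRatio(sample, math.nan, math.nan, math.nan,
                                   tuple(flags) + ("skipped",)))
            continue
        ts = quantities["TEL"] / quantities["SCG"]
        results.append(TSRatio(sample, quantities["TEL"], quantities["SCG"],
                               ts, tuple(flags)))

    if reference is not None:
        by_sample = {r.sample: r for r in results}
        if reference not in by_sample or not np.isfinite(by_sample[reference].ts):
            raise PlateError(f"reference sample {reference!r} has no T/S")
        ref_ts = by_sample[reference].ts
        results = [
            TSRatio(r.sample, r.t_quantity, r.s_quantity,
                    r.ts / ref_ts if np.isfinite(r.ts) else r.ts, r.qc_flags)
            for r in results
        ]
    return results


def ts_table(results: list[TSRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample, r.t_quantity, r.s_quantity, r.ts,
          ";".join(r.qc_flags)) for r in results],
        columns=["sample", "t_quantity", "s_quantity", "ts", "flags"],
    )


def simulate_plate(true_ts: dict[str, float], *,
                   tel_curve: tuple[float, float] = (PERFECT_DOUBLING_SLOPE, 22.0),
                   scg_curve: tuple[float, float] = (PERFECT_DOUBLING_SLOPE, 28.0),
                   input_ng: float = 25.0,
                   noise_sd: float = 0.0,
                   n_replicates: int = 3,
                   standard_quantities=DEFAULT_STANDARD_QUANTITIES,
                   seed: int = 0) -> PlateData:
    """Forward-simulate one plate from the standard-curve model.

    Each sample contributes ``input_ng`` of single-copy signal and
    ``ts * input_ng`` of telomere signal; well Cts are computed from the
    given (slope, intercept) curves with optional Gaussian noise.  Used
    as the synthetic fixture for round-trip checks of the quantification
    chain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([3, seed]))
    curves = {"TEL": tel_curve, "SCG": scg_curve}
    rows = []
    well = 0

    def ct_for(target: str, q: float) -> float:
        slope, intercept = curves[target]
        ct = slope * math.log10(q) + intercept
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd)
        return ct

    for target in TARGETS:
        for q in standard_quantities:
            for _ in range(n_replicates):
                well += 1
                rows.append((f"W{well:03d}", f"std_{target}", target,
                             "standard", ct_for(target, q), q))
    for sample, ts in true_ts.items():
        for target, q in (("TEL", ts * input_ng), ("SCG", input_ng)):
            for _ in range(n_replicates):
                well += 1
                rows.append((f"W{well:03d}", sample, target, "unknown",
                             ct_for(target, q), np.nan))
    return PlateData(pd.DataFrame(
        rows, columns=["well", "sample", "target", "role", "ct", "quantity_ng"]
    ))
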