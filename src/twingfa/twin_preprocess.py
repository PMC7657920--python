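"""Turn twin-level data into model-ready within-pair difference matrices.

The co-twin control design works on within-pair contrasts: for every
pair the heavier twin (by BMI) is identified and, for each variable,
the leaner twin's value is subtracted from the heavier twin's value.
Variables that are constant within a pair — genotype dosage (MZ twins
share their genome), age, sex, study year, liver-fat discordance — are
passed through as the shared value instead of a (zero) difference.

Filtering rules applied before modelling:

* columns with more than 50% missing values are dropped (all views);
  the cytokine panel additionally applies a 25% missingness cut at the
  twin level, before differencing;
* SNP columns carried by too few (<= 3) or too many (> 38) pairs are
  removed — such near-absent or near-universal risk alleles cannot
  explain within-pair differences;
* every view except genotype is centered and scaled to unit column
  variance; the genotype view enters the model untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortError, RunConfig, TwinCohortTable
from .gfa_model import ViewData

__all__ = [
    "PreprocessError",
    "BMITieError",
    "DifferenceMatrix",
    "order_pairs_by_bmi",
    "encode_smoking_onehot",
    "compute_pair_differences",
    "filter_missing",
    "filter_snp_carriers",
    "standardize_views",
    "preprocess_pipeline",
]

SMOKING_LEVELS = ("never", "former", "current")
PAIR_CONSTANT_TOL = 1e-9


class PreprocessError(ValueError):
    pass


class BMITieError(PreprocessError):
    """Raised when a pair has exactly equal BMI and no tie-break is configured."""


@dataclass
class DifferenceMatrix:
    """One model-ready view: pairs x variables.

    ``values`` holds heavier-minus-leaner differences (or shared values
    for pair-constant variables), indexed by pair id.  ``scaling``
    records the per-column center/scale applied by
    :func:`standardize_views` (None before scaling) so the transform is
    exactly invertible.
    """

    values: pd.DataFrame
    view: str
    scaling: pd.DataFrame | None = None

    @property
    def pair_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def var_names(self) -> list[str]:
        return list(self.values.columns)

    def to_view_data(self) -> ViewData:
        return ViewData(
            X=self.values.to_numpy(dtype=float),
            name=self.view,
            var_names=self.var_names,
        )

    def copy(self) -> "DifferenceMatrix":
        return DifferenceMatrix(
            values=self.values.copy(),
            view=self.view,
            scaling=None if self.scaling is None else self.scaling.copy(),
        )


def order_pairs_by_bmi(
    cohort: TwinCohortTable,
    tie_break: str | None = None,
    discordance_threshold: float = 3.0,
) -> pd.DataFrame:
    """Designate the heavier and leaner twin of every pair by BMI.

    Returns a frame indexed by ``pair_id`` (sorted lexicographically,
    the canonical pair order used everywhere downstream) with columns
    ``heavier_id, leaner_id, delta_bmi, discordant``.  ``discordant``
    flags pairs beyond the BMI-discordance threshold (default
    3 kg m^-2).  An exact BMI tie raises unless ``tie_break`` names a
    secondary variable ("sample_id" always works as a last resort).
    """
    bmi = cohort.data[cohort.bmi_variable]
    rows = []
    for pid in sorted(cohort.pair_ids.unique()):
        twins = cohort.pair_ids.index[cohort.pair_ids == pid].tolist()
        a, b = twins
        if bmi[a] == bmi[b]:
            if tie_break is None:
                raise BMITieError(
                    f"pair {pid!r} has an exact BMI tie ({bmi[a]}); set an explicit "
                    "tie-break variable (e.g. 'weight' or 'sample_id') in the config"
                )
            if tie_break == "sample_id":
                key = {a: a, b: b}
            else:
                if tie_break not in cohort.data.columns:
                    raise PreprocessError(f"tie-break variable {tie_break!r} not in data")
                key = {a: (cohort.data.loc[a, tie_break], a),
                       b: (cohort.data.loc[b, tie_break], b)}
            heavier, leaner = (a, b) if key[a] > key[b] else (b, a)
        else:
            heavier, leaner = (a, b) if bmi[a] > bmi[b] else (b, a)
        delta = float(bmi[heavier] - bmi[leaner])
        rows.append(
            {
                "pair_id": pid,
                "heavier_id": heavier,
                "leaner_id": leaner,
                "delta_bmi": delta,
                "discordant": delta > discordance_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")


def encode_smoking_onehot(
    cohort: TwinCohortTable, variable: str = "smoking"
) -> TwinCohortTable:
    """Replace a never/former/current column with three 0/1 indicator columns.

    The new columns (``smoking.never`` etc.) sum to 1 where the status
    is observed and are all missing where it is missing; after
    differencing they take values in {-1, 0, 1}.  Metadata rows are
    rewritten accordingly.  No-op if ``variable`` is absent.
    """
    if variable not in cohort.data.columns:
        return cohort
    col = cohort.data[variable]
    observed = col.dropna()
    unknown = set(observed.unique()) - set(SMOKING_LEVELS)
    if unknown:
        raise PreprocessError(
            f"unknown smoking level(s) {sorted(unknown)}; expected {SMOKING_LEVELS}"
        )
    data = cohort.data.drop(columns=[variable]).copy()
    for level in SMOKING_LEVELS:
        newcol = col.map(lambda v: np.nan if pd.isna(v) else float(v == level))
        data[f"{variable}.{level}"] = newcol
    meta = cohort.meta[cohort.meta["name"] != variable].copy()
    src = cohort.meta[cohort.meta["name"] == variable]
    view = src["view"].iloc[0] if len(src) else "clinical"
    add = pd.DataFrame(
        {
            "name": [f"{variable}.{lvl}" for lvl in SMOKING_LEVELS],
            "view": view,
            "vtype": "binary",
            "pair_constant": False,
            "units": "0 = no, 1 = yes",
        }
    )
    meta = pd.concat([meta, add], ignore_index=True)
    return TwinCohortTable(
        data=data, pair_ids=cohort.pair_ids, meta=meta, bmi_variable=cohort.bmi_variable
    )


def compute_pair_differences(
    cohort: TwinCohortTable,
    pair_order: pd.DataFrame,
    views: tuple[str, ...] | None = None,
) -> dict[str, DifferenceMatrix]:
    """Build one pairs x variables matrix per view.

    Non-pair-constant variables carry heavier minus leaner (missing if
    either twin is missing); pair-constant variables carry the shared
    value taken from the heavier twin (missing if that twin is
    missing), with a hard error if the two twins actually disagree.
    """
    if views is None:
        views = tuple(pd.unique(cohort.meta["view"]))
    pair_index = pair_order.index
    heavier = pair_order["heavier_id"]
    leaner = pair_order["leaner_id"]
    out: dict[str, DifferenceMatrix] = {}
    for view in views:
        cols = cohort.view_columns(view)
        if not cols:
            continue
        sub = cohort.data[cols].astype(float)
        hv = sub.loc[heavier].to_numpy()
        lv = sub.loc[leaner].to_numpy()
        meta_pc = (
            cohort.meta.set_index("name").loc[cols, "pair_constant"].to_numpy(dtype=bool)
        )
        diff = hv - lv
        if meta_pc.any():
            both = ~np.isnan(hv[:, meta_pc]) & ~np.isnan(lv[:, meta_pc])
            dev = np.abs(np.where(both, diff[:, meta_pc], 0.0))
            if np.any(dev > PAIR_CONSTANT_TOL):
                j = int(np.argwhere(dev > PAIR_CONSTANT_TOL)[0, 1])
                name = np.asarray(cols)[meta_pc][j]
                raise PreprocessError(
                    f"pair-constant variable {name!r} differs within a pair"
                )
        vals = np.where(meta_pc[None, :], hv, diff)
        frame = pd.DataFrame(vals, index=pair_index, columns=cols)
        frame.index.name = "pair_id"
        out[view] = DifferenceMatrix(values=frame, view=view)
    return out


def filter_missing(
    view: DifferenceMatrix | pd.DataFrame,
    max_missing_frac: float = 0.5,
) -> tuple[DifferenceMatrix | pd.DataFrame, pd.DataFrame]:
    """Drop columns whose missing fraction strictly exceeds the threshold.

    Works on a difference matrix or any twin-level frame (the cytokine
    25% rule is applied at twin level before differencing).  Returns
    the filtered object plus a report of dropped variables.
    """
    if not 0 <= max_missing_frac <= 1:
        raise PreprocessError("max_missing_frac must lie in [0, 1]")
    frame = view.values if isinstance(view, DifferenceMatrix) else view
    frac = frame.isna().mean(axis=0)
    dropped = frac[frac > max_missing_frac]
    report = pd.DataFrame(
        {
            "variable": dropped.index,
            "rule": f"missing_frac > {max_missing_frac:g}",
            "statistic": dropped.values,
        }
    )
    kept = frame.drop(columns=dropped.index)
    if kept.shape[1] == 0:
        warnings.warn("missingness filter removed every column", stacklevel=2)
    if isinstance(view, DifferenceMatrix):
        return DifferenceMatrix(values=kept, view=view.view, scaling=view.scaling), report
    return kept, report


def filter_snp_carriers(
    genotype_view: DifferenceMatrix,
    min_carrier_pairs: int = 4,
    max_carrier_pairs: int = 38,
) -> tuple[DifferenceMatrix, pd.DataFrame]:
    """Remove SNPs carried by too few or too many pairs.

    A pair "carries" a SNP when its (shared) risk-allele dosage is
    nonzero.  Columns with <= ``min_carrier_pairs - 1`` or
    > ``max_carrier_pairs`` carrier pairs are dropped: the defaults
    remove SNPs present in three or fewer pairs and in more than 38 of
    the 43 pairs.
    """
    vals = genotype_view.values
    arr = vals.to_numpy(dtype=float)
    obs = ~np.isnan(arr)
    ok = np.isin(arr[obs], (0.0, 1.0, 2.0))
    if not ok.all():
        bad = np.unique(arr[obs][~ok])
        raise PreprocessError(f"non-dosage genotype value(s): {bad}")
    carriers = np.nansum(arr > 0, axis=0).astype(int)
    drop = (carriers < min_carrier_pairs) | (carriers > max_carrier_pairs)
    report = pd.DataFrame(
        {
            "variable": vals.columns[drop],
            "rule": f"carrier_pairs < {min_carrier_pairs} or > {max_carrier_pairs}",
            "statistic": carriers[drop],
        }
    )
    kept = vals.loc[:, ~drop]
    return (
        DifferenceMatrix(values=kept, view=genotype_view.view, scaling=genotype_view.scaling),
        report,
    )


def standardize_views(
    views: dict[str, DifferenceMatrix],
    skip_views: tuple[str, ...] = ("genotype",),
    center: bool = True,
) -> dict[str, DifferenceMatrix]:
    """Scale every view except those in ``skip_views`` to unit column variance.

    Columns are mean-centered first (configurable), using observed
    entries only; the applied center/scale pair is recorded per column
    so the transform can be inverted exactly.  Zero-variance columns
    cannot be scaled and are dropped with a warning.  Skipped views are
    returned bit-identical, with an identity scaling record.
    """
    out: dict[str, DifferenceMatrix] = {}
    for name, dm in views.items():
        if name in skip_views:
            rec = pd.DataFrame(
                {"center": 0.0, "scale": 1.0}, index=dm.values.columns
            )
            out[name] = DifferenceMatrix(values=dm.values, view=dm.view, scaling=rec)
            continue
        vals = dm.values
        mu = vals.mean(axis=0, skipna=True) if center else pd.Series(0.0, index=vals.columns)
        sd = vals.std(axis=0, ddof=1, skipna=True)
        degenerate = ~(sd > 0) | sd.isna()
        if degenerate.any():
            warnings.warn(
                f"view {name!r}: dropping zero-variance column(s) "
                f"{vals.columns[degenerate].tolist()}",
                stacklevel=2,
            )
            vals = vals.loc[:, ~degenerate]
            mu, sd = mu[~degenerate], sd[~degenerate]
        scaled = (vals - mu) / sd
        rec = pd.DataFrame({"center": mu, "scale": sd})
        out[name] = DifferenceMatrix(values=scaled, view=dm.view, scaling=rec)
    return out


def invert_scaling(dm: DifferenceMatrix) -> pd.DataFrame:
    """Undo :func:`standardize_views` using the recorded center/scale."""
    if dm.scaling is None:
        return dm.values
    return dm.values * dm.scaling["scale"] + dm.scaling["center"]


@dataclass
class PreprocessResult:
    views: dict[str, DifferenceMatrix]
    raw_views: dict[str, DifferenceMatrix]
    pair_order: pd.DataFrame
    reports: pd.DataFrame

    def to_view_data(self) -> list[ViewData]:
        return [dm.to_view_data() for dm in self.views.values()]


def preprocess_pipeline(
    cohort: TwinCohortTable, config: RunConfig | None = None
) -> PreprocessResult:
    """Full preprocessing chain from twin-level cohort to model inputs.

    Order of operations: one-hot encode smoking, apply the cytokine
    twin-level missingness cut, order pairs by BMI, difference, apply
    the per-view missingness filter, the SNP carrier filter, then
    center and scale everything except genotype.
    """
    config = config or RunConfig()
    cohort = encode_smoking_onehot(cohort)

    reports = []
    cyto_cols = cohort.view_columns("cytokine")
    if cyto_cols:
        kept, rep = filter_missing(
            cohort.data[cyto_cols], config.cytokine_max_missing_frac
        )
        rep["view"] = "cytokine"
        rep["stage"] = "twin-level"
        reports.append(rep)
        dropped = set(cyto_cols) - set(kept.columns)
        if dropped:
            cohort = TwinCohortTable(
                data=cohort.data.drop(columns=sorted(dropped)),
                pair_ids=cohort.pair_ids,
                meta=cohort.meta[~cohort.meta["name"].isin(dropped)],
                bmi_variable=cohort.bmi_variable,
            )

    pair_order = order_pairs_by_bmi(cohort, tie_break=config.bmi_tie_break)
    views = compute_pair_differences(cohort, pair_order, views=config.views)

    filtered: dict[str, DifferenceMatrix] = {}
    for name, dm in views.items():
        dm2, rep = filter_missing(dm, config.max_missing_frac)
        rep["view"] = name
        rep["stage"] = "pair-level"
        reports.append(rep)
        filtered[name] = dm2
    if "genotype" in filtered:
        filtered["genotype"], rep = filter_snp_carriers(
            filtered["genotype"],
            config.snp_min_carrier_pairs,
            config.snp_max_carrier_pairs,
        )
        rep["view"] = "genotype"
        rep["stage"] = "pair-level"
        reports.append(rep)

    raw_views = {k: dm.copy() for k, dm in filtered.items()}
    scaled = standardize_views(filtered, center=config.center_columns)
    report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["variable", "rule", "statistic", "view", "stage"])
    )
    return PreprocessResult(
        views=scaled, raw_views=raw_views, pair_order=pair_order, reports=report
    )
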