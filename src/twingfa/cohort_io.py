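"""Reading, validating and writing twin-cohort tables and model results.

File conventions (all delimited text, UTF-8, "." decimal):

* per-view matrices — CSV, first column ``sample_id``, header row of
  variable names; empty cell or ``NA`` means missing;
* pair map — CSV with columns ``sample_id, pair_id``;
* variable metadata — CSV with columns
  ``name, view, vtype, pair_constant, units``;
* results — one CSV per table plus a JSON run manifest, floats printed
  to 10 significant digits so that re-reading reproduces the written
  values at the printed precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VIEWS",
    "CohortError",
    "TwinCohortTable",
    "RunConfig",
    "read_cohort",
    "read_matrix",
    "write_cohort",
    "write_results",
    "read_results_table",
    "write_manifest",
    "save_posterior",
    "load_posterior",
]

VIEWS = ("clinical", "cytokine", "genotype", "methylation", "dietary")
VTYPES = ("continuous", "binary", "categorical", "dosage")
_NA_VALUES = ["", "NA"]
_FLOAT_FMT = "%.10g"


class CohortError(ValueError):
    """Raised on any cohort-file validation failure."""


@dataclass
class TwinCohortTable:
    """Twin-level observations with pair structure.

    ``data`` has one row per twin (indexed by ``sample_id``) and one
    column per variable, across all views; ``pair_ids`` maps each
    sample to its pair.  Invariants: unique sample ids, every pair id
    occurring exactly twice, and a non-missing BMI column for ordering
    heavier/leaner within each pair.
    """

    data: pd.DataFrame
    pair_ids: pd.Series
    meta: pd.DataFrame
    bmi_variable: str = "bmi"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise CohortError(f"duplicate sample_id(s): {dups}")
        missing_map = set(self.data.index) - set(self.pair_ids.index)
        if missing_map:
            raise CohortError(f"samples absent from pair map: {sorted(missing_map)}")
        extra = set(self.pair_ids.index) - set(self.data.index)
        if extra:
            raise CohortError(
                f"pair map lists samples absent from the matrices: {sorted(extra)}"
            )
        counts = self.pair_ids.value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise CohortError(
                f"every pair_id must occur exactly twice; offending pair(s): "
                f"{bad.index.tolist()}"
            )
        if self.bmi_variable not in self.data.columns:
            raise CohortError(f"BMI variable {self.bmi_variable!r} not in data")
        if self.data[self.bmi_variable].isna().any():
            bad_s = self.data.index[self.data[self.bmi_variable].isna()].tolist()
            raise CohortError(f"missing BMI for sample(s): {bad_s}")
        meta_names = set(self.meta["name"])
        orphans = [c for c in self.data.columns if c not in meta_names]
        if orphans:
            raise CohortError(f"variables without metadata: {orphans}")

    @property
    def n_twins(self) -> int:
        return len(self.data)

    @property
    def n_pairs(self) -> int:
        return self.pair_ids.nunique()

    def view_columns(self, view: str) -> list[str]:
        names = self.meta.loc[self.meta["view"] == view, "name"]
        return [n for n in names if n in self.data.columns]


@dataclass
class RunConfig:
    """Full pipeline configuration; the defaults reproduce the reference
    protocol (K=40, 2000 iterations, 90% burn-in, noise target 1/3)."""

    K: int = 40
    n_iter: int = 2000
    burnin_frac: float = 0.9
    noise_target: float = 1.0 / 3.0
    seed: int = 0
    views: tuple[str, ...] = VIEWS
    max_missing_frac: float = 0.5
    cytokine_max_missing_frac: float = 0.25
    snp_min_carrier_pairs: int = 4
    snp_max_carrier_pairs: int = 38
    center_columns: bool = True
    bmi_tie_break: str | None = None
    a_pi: float = 1.0
    b_pi: float = 1.0
    a_alpha: float = 1e-3
    b_alpha: float = 1e-3
    a_tau: float = 14.0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_iter < 1:
            raise CohortError("K and n_iter must be positive")
        if not 0 < self.burnin_frac < 1:
            raise CohortError("burnin_frac must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["views"] = list(self.views)
        return d


def _read_csv(path: Path | str, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"file not found: {path}")
    return pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False, **kw)


def read_matrix(path: Path | str) -> pd.DataFrame:
    """Read one samples x variables matrix (first column = sample_id)."""
    df = _read_csv(path)
    if df.columns[0] != "sample_id":
        raise CohortError(f"{path}: first column must be 'sample_id'")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    # numeric columns become float; categorical (e.g. smoking) stay strings
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c]).astype(float)
        except (ValueError, TypeError):
            pass
    return df


def read_cohort(
    matrix_files: Mapping[str, Path | str],
    pair_map_file: Path | str,
    meta_file: Path | str,
    bmi_variable: str = "bmi",
) -> TwinCohortTable:
    """Read per-view matrices, the pair map and variable metadata.

    Samples are aligned across views by sample id; every view must
    cover the same samples.  Missing entries (empty cells or ``NA``)
    are preserved as missing — no imputation happens here.
    """
    meta = _read_csv(meta_file)
    required = {"name", "view", "vtype", "pair_constant"}
    if not required.issubset(meta.columns):
        raise CohortError(f"metadata must have columns {sorted(required)}")
    bad_view = set(meta["view"]) - set(VIEWS)
    if bad_view:
        raise CohortError(f"unknown view(s) in metadata: {sorted(bad_view)}")
    bad_vtype = set(meta["vtype"]) - set(VTYPES)
    if bad_vtype:
        raise CohortError(f"unknown vtype(s) in metadata: {sorted(bad_vtype)}")
    dosage_outside = meta[(meta["vtype"] == "dosage") & (meta["view"] != "genotype")]
    if len(dosage_outside):
        raise CohortError(
            f"dosage variables outside the genotype view: {dosage_outside['name'].tolist()}"
        )
    meta["pair_constant"] = meta["pair_constant"].astype(bool)

    pair_map = _read_csv(pair_map_file)
    if not {"sample_id", "pair_id"}.issubset(pair_map.columns):
        raise CohortError("pair map must have columns sample_id, pair_id")
    pair_ids = pd.Series(
        pair_map["pair_id"].astype(str).values,
        index=pair_map["sample_id"].astype(str).values,
        name="pair_id",
    )
    if pair_ids.index.duplicated().any():
        raise CohortError("duplicate sample_id in pair map")

    frames = []
    sample_index = None
    for view, path in matrix_files.items():
        df = read_matrix(path)
        if sample_index is None:
            sample_index = df.index
        elif not sample_index.equals(df.index):
            if set(sample_index) == set(df.index):
                df = df.loc[sample_index]
            else:
                diff = set(sample_index) ^ set(df.index)
                raise CohortError(
                    f"view {view!r}: sample set differs from other views: {sorted(diff)}"
                )
        dup = [c for c in df.columns if c in {c2 for f in frames for c2 in f.columns}]
        if dup:
            raise CohortError(f"view {view!r}: duplicate variable name(s) {dup}")
        frames.append(df)
    if not frames:
        raise CohortError("no matrix files given")
    data = pd.concat(frames, axis=1)
    return TwinCohortTable(
        data=data, pair_ids=pair_ids, meta=meta, bmi_variable=bmi_variable
    )


def write_cohort(cohort: TwinCohortTable, outdir: Path | str) -> dict[str, Path]:
    """Write a twin-level cohort in the package's CSV conventions.

    One matrix per view plus ``pair_map.csv`` and ``meta.csv``; the
    inverse of :func:`read_cohort`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for view in pd.unique(cohort.meta["view"]):
        cols = cohort.view_columns(view)
        if not cols:
            continue
        p = outdir / f"{view}.csv"
        cohort.data[cols].to_csv(p, float_format=_FLOAT_FMT, index_label="sample_id")
        written[view] = p
    pm = cohort.pair_ids.rename_axis("sample_id").reset_index()
    p = outdir / "pair_map.csv"
    pm.to_csv(p, index=False)
    written["pair_map"] = p
    p = outdir / "meta.csv"
    cohort.meta.to_csv(p, index=False)
    written["meta"] = p
    return written


def save_posterior(posterior, path: Path | str) -> Path:
    """Archive a posterior summary (draws + streaming moments) as .npz."""
    path = Path(path)
    payload: dict = {
        "h_draws": posterior.h_draws,
        "pi_draws": posterior.pi_draws,
        "z_draws": posterior.z_draws,
        "log_joint_trace": posterior.log_joint_trace,
        "view_names": np.asarray(posterior.view_names, dtype=object),
    }
    for m, view in enumerate(posterior.view_names):
        payload[f"w_mean_{view}"] = posterior.w_mean[m]
        payload[f"w_var_{view}"] = posterior.w_var[m]
        payload[f"tau_mean_{view}"] = posterior.tau_mean[m]
        payload[f"alpha_mean_{view}"] = posterior.alpha_mean[m]
        vn = posterior.var_names[m]
        if vn is not None:
            payload[f"var_names_{view}"] = np.asarray(list(vn), dtype=object)
    if posterior.pair_ids is not None:
        payload["pair_ids"] = np.asarray(list(posterior.pair_ids), dtype=object)
    np.savez_compressed(path, **payload)
    return path


def load_posterior(path: Path | str):
    """Inverse of :func:`save_posterior`."""
    from .gibbs_sampler import PosteriorSummary

    with np.load(path, allow_pickle=True) as z:
        view_names = [str(v) for v in z["view_names"]]
        var_names = []
        for view in view_names:
            key = f"var_names_{view}"
            var_names.append([str(s) for s in z[key]] if key in z else None)
        return PosteriorSummary(
            h_draws=z["h_draws"],
            pi_draws=z["pi_draws"],
            z_draws=z["z_draws"],
            w_mean=[z[f"w_mean_{v}"] for v in view_names],
            w_var=[z[f"w_var_{v}"] for v in view_names],
            tau_mean=[z[f"tau_mean_{v}"] for v in view_names],
            alpha_mean=[z[f"alpha_mean_{v}"] for v in view_names],
            log_joint_trace=z["log_joint_trace"],
            view_names=view_names,
            var_names=var_names,
            pair_ids=(
                [str(s) for s in z["pair_ids"]] if "pair_ids" in z else None
            ),
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_results_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_manifest(path: Path | str, payload: dict) -> None:
    payload = dict(payload)
    payload.setdefault("gamma_convention", "shape-rate")
    from . import __version__

    payload.setdefault("software_version", __version__)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def write_results(posterior, outdir: Path | str, config: RunConfig | None = None) -> list[Path]:
    """Write posterior summary tables as CSV plus a run manifest.

    Emits one loading matrix per view (variables x components,
    posterior means), the score matrix (pairs x components), the
    activity matrix (views x components, posterior inclusion
    probabilities), the pi summary, per-variable residual variances,
    and ``manifest.json``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise CohortError(f"output directory not writable: {outdir}") from exc

    K = posterior.pi_draws.shape[1]
    comp_names = [f"comp{k:02d}" for k in range(K)]
    written: list[Path] = []

    for m, view in enumerate(posterior.view_names):
        vn = posterior.var_names[m]
        idx = list(vn) if vn is not None else [f"v{d}" for d in range(posterior.w_mean[m].shape[0])]
        df = pd.DataFrame(posterior.w_mean[m], index=idx, columns=comp_names)
        df.index.name = "variable"
        p = outdir / f"loadings_{view}.csv"
        _write_table(df, p)
        written.append(p)
        rv = pd.DataFrame(
            {"residual_variance": 1.0 / posterior.tau_mean[m]}, index=idx
        )
        rv.index.name = "variable"
        p = outdir / f"residual_variance_{view}.csv"
        _write_table(rv, p)
        written.append(p)

    pair_idx = (
        list(posterior.pair_ids)
        if posterior.pair_ids is not None
        else [f"pair{n:03d}" for n in range(posterior.z_mean.shape[0])]
    )
    scores = pd.DataFrame(posterior.z_mean, index=pair_idx, columns=comp_names)
    scores.index.name = "pair_id"
    p = outdir / "scores.csv"
    _write_table(scores, p)
    written.append(p)

    act = pd.DataFrame(posterior.activity, index=posterior.view_names, columns=comp_names)
    act.index.name = "view"
    p = outdir / "activity.csv"
    _write_table(act, p)
    written.append(p)

    pi = pd.DataFrame(
        {
            "pi_mean": posterior.pi_draws.mean(axis=0),
            "pi_sd": posterior.pi_draws.std(axis=0, ddof=1),
        },
        index=comp_names,
    )
    pi.index.name = "component"
    p = outdir / "pi.csv"
    _write_table(pi, p)
    written.append(p)

    manifest: dict = {
        "n_retained_draws": int(posterior.n_retained),
        "views": list(posterior.view_names),
    }
    if posterior.config is not None:
        manifest.update(
            n_iter=posterior.config.n_iter,
            burnin_frac=posterior.config.burnin_frac,
            seed=posterior.config.seed,
            thinning=posterior.config.thinning,
        )
    if posterior.hyper is not None:
        manifest["K"] = posterior.hyper.K
        manifest["noise_target"] = posterior.hyper.noise_target
    if config is not None:
        manifest["run_config"] = config.to_dict()
    p = outdir / "manifest.json"
    write_manifest(p, manifest)
    written.append(p)
    return written
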