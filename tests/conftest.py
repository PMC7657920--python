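import numpy as np
import pandas as pd
import pytest

from twingfa.cohort_io import RunConfig
from twingfa.gfa_model import GFAHyperparams
from twingfa.gibbs_sampler import ChainConfig, run_chain
from twingfa.synthetic_data import SimCohortConfig, simulate_difference_views


def write_toy_cohort(tmp_path, n_pairs=2, missing_cell=None):
    """Write a tiny 2-view cohort (clinical + cytokine) as CSV files.

    Returns (matrix_files, pair_map_file, meta_file).  ``missing_cell``
    optionally blanks one (sample, variable) cell of the clinical file.
    """
    samples = [f"P{p}_{t}" for p in range(n_pairs) for t in "ab"]
    rng = np.random.default_rng(7)
    clinical = pd.DataFrame(
        {
            "bmi": 25 + np.arange(len(samples), dtype=float),
            "weight": 70 + rng.normal(0, 5, len(samples)).round(1),
            "crp": rng.normal(2, 1, len(samples)).round(2),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    cytokine = pd.DataFrame(
        {
            "il6": rng.normal(0, 1, len(samples)).round(3),
            "tnf": rng.normal(0, 1, len(samples)).round(3),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    if missing_cell is not None:
        clinical.loc[missing_cell] = np.nan
    cpath = tmp_path / "clinical.csv"
    kpath = tmp_path / "cytokine.csv"
    clinical.to_csv(cpath)
    cytokine.to_csv(kpath)
    pair_map = pd.DataFrame(
        {"sample_id": samples, "pair_id": [f"P{p}" for p in range(n_pairs) for _ in "ab"]}
    )
    ppath = tmp_path / "pair_map.csv"
    pair_map.to_csv(ppath, index=False)
    meta = pd.DataFrame(
        {
            "name": ["bmi", "weight", "crp", "il6", "tnf"],
            "view": ["clinical"] * 3 + ["cytokine"] * 2,
            "vtype": ["continuous"] * 5,
            "pair_constant": [False] * 5,
            "units": ["kg m^-2", "kg", "mg l^-1", "", ""],
        }
    )
    mpath = tmp_path / "meta.csv"
    meta.to_csv(mpath, index=False)
    return {"clinical": cpath, "cytokine": kpath}, ppath, mpath


@pytest.fixture
def toy_cohort_files(tmp_path):
    return write_toy_cohort(tmp_path)


@pytest.fixture(scope="session")
def small_fit():
    """A short but converged fit on a small simulated dataset.

    Shared across tests that only need *a* valid posterior (shapes,
    I/O, reporting), not a particular scientific property.
    """
    mask = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
    cfg = SimCohortConfig(
        n_pairs=40, k_true=3, activity_mask=mask, missing_rates={}, seed=11,
        dims={"a": 8, "b": 10},
    )
    views, truth = simulate_difference_views(cfg, dims=[8, 10], view_names=["a", "b"])
    for v in views:
        v.X = (v.X - v.X.mean(0)) / v.X.std(0, ddof=1)
    post = run_chain(
        views,
        GFAHyperparams(K=6),
        ChainConfig(n_iter=400, burnin_frac=0.8, seed=5),
    )
    return views, truth, post
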