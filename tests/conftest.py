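import warnings

import numpy as np
import pandas as pd
import pytest

from methdecon import BetaMatrix, simulate_cell_methylomes, simulate_cohort


@pytest.fixture(scope="session")
def tiny_beta():
    """3 probes x 2 samples, hand-written values."""
    return BetaMatrix(
        pd.Index(["cg1", "cg2", "cg3"]),
        pd.Index(["s1", "s2"]),
        np.array([[0.1, 0.2], [0.5, 0.6], [0.9, 1.0]]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 3-cell-type cohort with 20 spiked probes, fixed seed."""
    M = simulate_cell_methylomes(400, 3, separation=0.6, seed=11)
    rng = np.random.default_rng(11)
    spiked = sorted(rng.choice(400, 20, replace=False).tolist())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        betas, sheet, truth = simulate_cohort(
            M, 40, 40, spiked_probes=spiked, delta=0.3, noise_sd=0.1, seed=12
        )
    return betas, sheet, truth


@pytest.fixture(scope="session")
def breast_cohort_sheet():
    """Sample sheet reproducing a 523-tumor breast cohort: per-subtype
    counts with early/late/missing stage splits, 18 Normal-like tumors
    and 124 adjacent normals."""
    from methdecon.io import validate_sample_sheet

    counts = {
        # subtype: (early, late, missing-stage)
        "Basal-like": (70, 14, 2),
        "Her2": (20, 10, 1),
        "LumA": (207, 69, 3),
        "LumB": (84, 42, 1),
    }
    rows = []
    i = 0
    for subtype, (n_early, n_late, n_miss) in counts.items():
        for n, stages in ((n_early, ["I", "II"]), (n_late, ["III", "IV"]),
                          (n_miss, ["missing"])):
            for j in range(n):
                rows.append([f"t{i}", "tumor", subtype,
                             stages[j % len(stages)], 60.0])
                i += 1
    for j in range(18):
        rows.append([f"nl{j}", "tumor", "Normal-like", "I", 60.0])
    for j in range(124):
        rows.append([f"n{j}", "normal", None, None, None])
    return validate_sample_sheet(pd.DataFrame(
        rows, columns=["sample_id", "tissue_status", "subtype", "stage", "age"]
    ))


@pytest.fixture()
def toy_manifest():
    return pd.DataFrame({
        "probe_id": ["cg01", "cg02", "cg03", "cg04"],
        "chrom": ["chr1"] * 4,
        "pos": [100, 200, 300, 400],
        "gene_names": ["SAMD11;SAMD11", "KLHL17;PLEKHN1", "", "A;B;C"],
        "gene_groups": ["TSS1500;Body", "3'UTR;TSS1500", "", "Body;Body;TSS200"],
        "island_relation": ["Island", "N_Shore", "OpenSea", "S_Shelf"],
        "mask_snp": [False, False, False, False],
        "mask_crossreactive": [False, False, False, False],
        "mask_sex": [False, False, False, False],
    })
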