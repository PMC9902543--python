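import numpy as np
import pandas as pd
import pytest

from diaquant import DesignTable, SimConfig, simulate_experiment


@pytest.fixture
def small_design() -> DesignTable:
    rows = []
    for cond, n in {"B": 3, "V": 3}.items():
        for i in range(n):
            rows.append({"run_id": f"{cond}_{i + 1:02d}", "condition": cond,
                         "compartment": "lung"})
    return DesignTable(pd.DataFrame(rows))


@pytest.fixture
def write_report(tmp_path):
    """Write a long-format precursor report TSV and return its path."""

    def _write(rows, name="report.tsv",
               header=("Run", "Protein.Group", "Precursor.Id",
                       "Precursor.Quantity")):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def sim_experiment():
    """Small default-structure simulated experiment (records, design, truth)."""
    cfg = SimConfig(n_proteins=150, seed=42)
    return (cfg, *simulate_experiment(cfg))


def make_design(counts: dict[str, int], compartment: str = "lung"):
    rows = [{"run_id": f"{c}_{i + 1:02d}", "condition": c,
             "compartment": compartment}
            for c, n in counts.items() for i in range(n)]
    return DesignTable(pd.DataFrame(rows))


def planted_blobs(rng, n_per=50, sd=0.5, n_cols=4):
    """Three Gaussian blobs with centers ~10 blob-sds apart."""
    centers = np.array([[0.0, 0.0, 0.0, 0.0],
                        [5.0, 5.0, 0.0, 0.0],
                        [0.0, 0.0, 5.0, 5.0]])[:, :n_cols]
    X = np.vstack([c + rng.normal(0, sd, size=(n_per, n_cols))
                   for c in centers])
    labels = np.repeat(np.arange(3), n_per)
    profiles = pd.DataFrame(
        X, index=pd.Index([f"P{i:04d}" for i in range(len(X))],
                          name="protein_group"),
        columns=[f"c{j}" for j in range(n_cols)])
    return profiles, labels
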