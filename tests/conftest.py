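import numpy as np
import pandas as pd
import pytest

from peakladder import ChromSizes, SimulationConfig, simulate


@pytest.fixture(scope="session")
def toy_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture(scope="session")
def toy_genes() -> pd.DataFrame:
    """One 100 kb chromosome, TSS at 10/30/50/70/90 kb, up = {30 kb, 50 kb}."""
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(5)],
            "chrom": ["chr1"] * 5,
            "strand": ["+", "-", "+", "-", "+"],
            "tss": [10_000, 30_000, 50_000, 70_000, 90_000],
            "de_label": ["unchanged", "up", "up", "unchanged", "unchanged"],
            "chromatin_class": ["bivalent", "k4_only", "bivalent", "neither", None],
        }
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic bundle at generator defaults (shared, read-only)."""
    return simulate(SimulationConfig(seed=42))


def random_intervals(rng: np.random.Generator, n: int, domain: int = 10_000,
                     max_width: int = 500, chroms=("chr1",)) -> pd.DataFrame:
    starts = rng.integers(0, domain - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(list(chroms), size=n),
            "start": starts,
            "end": starts + widths,
        }
    )


def brute_force_overlap_any(queries: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """O(n*m) all-pairs overlap scan — the oracle for the sweep engine."""
    out = np.zeros(len(queries), dtype=bool)
    for i, (qc, qs, qe) in enumerate(zip(queries["chrom"], queries["start"], queries["end"])):
        for fc, fs, fe in zip(features["chrom"], features["start"], features["end"]):
            if qc == fc and qs < fe and fs < qe:
                out[i] = True
                break
    return out


def covered_bases_oracle(df: pd.DataFrame, domain: int = 12_000) -> int:
    """Per-base occupancy union size — the oracle for interval merging."""
    total = 0
    for chrom in df["chrom"].unique():
        occupied = np.zeros(domain, dtype=bool)
        sub = df[df["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            occupied[s:e] = True
        total += int(occupied.sum())
    return total
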