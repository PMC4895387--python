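import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methylpartition import Hyperparameters, LocusCounts
from methylpartition.io import MethylationTable, SampleSheet

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def hyper():
    return Hyperparameters()


@pytest.fixture
def oracle_fixture():
    """Six loci, coverage <= 6, 2+2 samples, with a concentrated posterior.

    Concentration is by design: the membership probabilities of each locus
    must be estimable from ~1e3 recorded sweeps to well within the 0.02
    oracle-comparison tolerance, which bounds the admissible per-entry
    Monte-Carlo variance p(1-p)/n_eff.
    """
    return [
        LocusCounts([6, 6], [0, 1], [6, 6], [5, 6]),  # strong hypo
        LocusCounts([6, 6], [5, 6], [6, 6], [0, 1]),  # strong hyper
        LocusCounts([6, 5], [1, 0], [6, 6], [4, 5]),  # hypo
        LocusCounts([6, 6], [4, 5], [6, 5], [1, 0]),  # hyper
        LocusCounts([6, 6], [1, 1], [6, 6], [5, 5]),  # strong hypo
        LocusCounts([6, 6], [5, 5], [6, 6], [1, 1]),  # strong hyper
    ]


@pytest.fixture
def ambiguous_fixture():
    """Six loci spanning strong, weak, low-coverage and degenerate evidence."""
    return [
        LocusCounts([6, 6], [0, 1], [6, 6], [5, 6]),
        LocusCounts([6, 6], [5, 6], [6, 6], [0, 1]),
        LocusCounts([5, 6], [3, 3], [6, 5], [3, 3]),
        LocusCounts([4, 3], [1, 1], [4, 4], [2, 3]),
        LocusCounts([1, 2], [0, 1], [2, 1], [1, 1]),
        LocusCounts([3, 3], [0, 0], [3, 2], [0, 0]),
    ]


@pytest.fixture
def l3_fixture():
    """Three loci (strong / symmetric / weak) for joint-state chain checks."""
    return [
        LocusCounts([6, 6], [0, 1], [6, 6], [5, 6]),
        LocusCounts([5, 6], [3, 3], [6, 5], [3, 3]),
        LocusCounts([4, 3], [1, 1], [4, 4], [2, 3]),
    ]


def random_small_locus(rng: np.random.Generator, max_cov: int = 8) -> LocusCounts:
    c1 = rng.integers(1, max_cov, size=2)
    c2 = rng.integers(1, max_cov, size=2)
    return LocusCounts(
        c1, rng.binomial(c1, rng.random()), c2, rng.binomial(c2, rng.random())
    )


@pytest.fixture
def two_plus_two_sheet():
    return SampleSheet(
        sample_ids=("case1", "case2", "control1", "control2"),
        conditions=("case", "case", "control", "control"),
    )


@pytest.fixture
def filter_table(two_plus_two_sheet):
    """Ten loci: 2 fully methylated, 1 unmethylated, 7 informative."""
    rows = [
        # chrom, pos, (meth, cov) x 4 samples
        ("chr1", 10, (3, 3), (4, 4), (2, 2), (5, 5)),    # fully methylated
        ("chr1", 20, (2, 2), (0, 0), (3, 3), (4, 4)),    # fully methylated (one uncovered)
        ("chr1", 30, (0, 4), (0, 3), (0, 5), (0, 2)),    # unmethylated
        ("chr1", 40, (0, 2), (3, 3), (1, 4), (2, 5)),    # informative (M = 0 and M = C mix)
        ("chr1", 50, (1, 4), (2, 5), (3, 4), (1, 3)),
        ("chr1", 60, (4, 6), (3, 6), (1, 6), (0, 6)),
        ("chr1", 70, (2, 3), (1, 2), (2, 4), (3, 3)),
        ("chr1", 80, (5, 8), (4, 7), (1, 8), (2, 7)),
        ("chr1", 90, (0, 5), (1, 5), (4, 5), (5, 5)),
        ("chr2", 15, (3, 5), (2, 4), (2, 5), (1, 4)),
    ]
    records = []
    sids = two_plus_two_sheet.sample_ids
    for chrom, pos, *pairs in rows:
        rec = {"chrom": chrom, "pos": pos}
        for sid, (m, c) in zip(sids, pairs):
            rec[f"meth_{sid}"] = m
            rec[f"cov_{sid}"] = c
        records.append(rec)
    return MethylationTable(frame=pd.DataFrame(records), sheet=two_plus_two_sheet)
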