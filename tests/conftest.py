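import numpy as np
import pandas as pd
import pytest

from cernet import (
    PlantedTriplet,
    SyntheticSpec,
    TripartiteNetwork,
    default_planted_triplets,
    simulate_dataset,
)
from cernet.containers import ExpressionMatrix
from cernet.triplets import CeRNATriplet, CorrelationResult


@pytest.fixture
def zero_noise_dataset():
    """One planted triplet, no noise: all correlation gates are forced."""
    spec = SyntheticSpec(
        n_case=3,
        n_control=3,
        n_lncRNA=4,
        n_miRNA=3,
        n_mRNA=5,
        planted_triplets=(PlantedTriplet("lnc-0001", "mir-0001", "mrna-0001", 2.0),),
        background_noise_sd=0.0,
        rng_seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture
def benchmark_spec():
    """The planted-recovery benchmark world: 10 triplets, sd 0.05, 12/group."""

    def make(seed: int) -> SyntheticSpec:
        return SyntheticSpec(
            n_case=12,
            n_control=12,
            planted_triplets=default_planted_triplets(10),
            background_noise_sd=0.05,
            rng_seed=seed,
        )

    return make


def build_network(edges, classes):
    """Network from (u, v) pairs and an id -> class mapping."""
    net = TripartiteNetwork()
    for n, cls in classes.items():
        net.add_node(n, cls)
    for u, v in edges:
        net.add_edge(u, v)
    return net


@pytest.fixture
def toy_network():
    """L-m1, L-m2; m1-g1, m1-g2, m2-g2 (pair-count example network)."""
    classes = {
        "L": "lncRNA",
        "m1": "miRNA",
        "m2": "miRNA",
        "g1": "mRNA",
        "g2": "mRNA",
    }
    edges = [("L", "m1"), ("L", "m2"), ("m1", "g1"), ("m1", "g2"), ("m2", "g2")]
    return build_network(edges, classes)


def expr_matrix(rows, samples=None, feature_class="mRNA", is_log2=True):
    """Small ExpressionMatrix helper; first half of samples are cases."""
    values = pd.DataFrame(rows).T if isinstance(rows, dict) else rows
    if isinstance(rows, dict):
        values = pd.DataFrame(
            {k: np.asarray(v, dtype=float) for k, v in rows.items()}
        ).T
    n = values.shape[1]
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    values.columns = samples
    half = n // 2
    groups = pd.Series(
        ["case"] * half + ["control"] * (n - half), index=samples
    )
    return ExpressionMatrix(
        values=values, feature_class=feature_class, groups=groups, is_log2=is_log2
    )


def random_tripartite(rng, n_lnc=3, n_mir=3, n_mrna=4, p=0.5):
    """Random typed network for oracle-equivalence tests."""
    classes = {}
    for i in range(n_lnc):
        classes[f"l{i}"] = "lncRNA"
    for i in range(n_mir):
        classes[f"m{i}"] = "miRNA"
    for i in range(n_mrna):
        classes[f"g{i}"] = "mRNA"
    net = TripartiteNetwork()
    for n, cls in classes.items():
        net.add_node(n, cls)
    lncs = [n for n, c in classes.items() if c == "lncRNA"]
    mirs = [n for n, c in classes.items() if c == "miRNA"]
    mrnas = [n for n, c in classes.items() if c == "mRNA"]
    for u, v in [(a, b) for a in lncs for b in mirs] + [
        (a, b) for a in mirs for b in mrnas
    ] + [(a, b) for a in lncs for b in mrnas]:
        if rng.random() < p:
            net.add_edge(u, v)
    return net


def make_triplet(lnc, mir, mrna):
    c = CorrelationResult(r=0.995, p_value=1e-6, n=6)
    neg = CorrelationResult(r=-0.9, p_value=1e-3, n=6)
    return CeRNATriplet(lnc, mir, mrna, lnc_mrna=c, mir_lnc=neg, mir_mrna=neg)
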