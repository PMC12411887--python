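"""Shared fixtures: the default synthetic study at fixed seeds."""

from __future__ import annotations

import pytest

from siampeat import (
    annotate_clusters,
    build_design,
    cluster_isotopologues,
    filter_features,
    generate_feature_table,
    generate_species,
)
from siampeat.synth import NoiseConfig


@pytest.fixture(scope="session")
def design():
    return build_design(replicates=2)


@pytest.fixture(scope="session")
def labeled_ids(design):
    return [s.sample_id for s in design if s.label_status == "labeled"]


@pytest.fixture(scope="session")
def unlabeled_ids(design):
    return [s.sample_id for s in design if s.label_status == "unlabeled"]


@pytest.fixture(scope="session")
def incubation_samples(design):
    """Incubated samples only (litter-only material excluded)."""
    return [s for s in design if s.treatment in ("PO", "PL")]


def make_study(seed: int, design, noise: NoiseConfig | None = None, n_species: int = 60):
    """Generate one synthetic study: species, table, truth, filtered table."""
    species = generate_species(n_species, seed=seed)
    table, truth = generate_feature_table(
        species, design, noise=noise or NoiseConfig(), seed=seed + 1000
    )
    filtered = filter_features(table)
    return {"species": species, "table": table, "truth": truth, "filtered": filtered}


@pytest.fixture(scope="session")
def default_studies(design):
    """Three default-noise studies at fixed seeds, with annotated clusters."""
    studies = []
    lab = [s.sample_id for s in design if s.label_status == "labeled"]
    unl = [s.sample_id for s in design if s.label_status == "unlabeled"]
    for seed in (1, 2, 3):
        st = make_study(seed, design)
        clusters = cluster_isotopologues(st["filtered"])
        annotate_clusters(clusters, sample_ids=lab, control_sample_ids=unl)
        st["clusters"] = clusters
        studies.append(st)
    return studies


@pytest.fixture(scope="session")
def noiseless_study(design):
    """One noiseless study (unfiltered table), with annotated clusters."""
    st = make_study(5, design, noise=NoiseConfig.noiseless())
    lab = [s.sample_id for s in design if s.label_status == "labeled"]
    unl = [s.sample_id for s in design if s.label_status == "unlabeled"]
    clusters = cluster_isotopologues(st["table"])
    annotate_clusters(clusters, sample_ids=lab, control_sample_ids=unl)
    st["clusters"] = clusters
    return st


def classification_confusion(studies, labeled_sample_ids, min_members: int = 2):
    """Pooled confusion counts of label calls vs ground truth.

    Restricted to clusters mapping to a true species, with at least
    ``min_members`` members and nonzero labeled-sample signal — a cluster
    whose labeled envelope lies wholly outside the analytical window has
    zero intensity in every labeled sample and carries no diagnostic
    information.
    """
    tp = fp = tn = fn = 0
    for st in studies:
        fmap = st["truth"].feature_map.set_index("feature_id")
        for c in st["clusters"]:
            sp = fmap.loc[c.base_feature.feature_id, "species_id"]
            if sp == "" or len(c.members) < min_members:
                continue
            labeled_signal = sum(
                rec.intensities.get(s, 0.0)
                for _, rec in c.members
                for s in labeled_sample_ids
            )
            if labeled_signal <= 0:
                continue
            if c.label_call and st["truth"].labeled[sp]:
                tp += 1
            elif c.label_call:
                fp += 1
            elif st["truth"].labeled[sp]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn
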