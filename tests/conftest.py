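from __future__ import annotations

import numpy as np
import pytest

from bgcnet.simulate import FamilySpec, FixtureConfig, default_config, write_fixture_set
from bgcnet.types import BiosyntheticGene, ClusterRecord, DomainAnnotation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170818)


def make_cluster(cluster_id="G01.cluster001", genome_id="G01", bgc_class="nrps",
                 genes=None, domains=None) -> ClusterRecord:
    """Hand-built three-gene NRPS cluster used across the I/O and
    architecture tests; gene 2 sits on the minus strand."""
    if genes is None:
        genes = [
            BiosyntheticGene("orf1", "+", 101, 400, "MKTAYIAKQRQISFVKSHFSRQLEERLGLIE",
                             is_biosynthetic=True,
                             sec_met_raw=("Type: nrps", "Kind: biosynthetic")),
            BiosyntheticGene("orf2", "-", 501, 800, "MSDNLYQRVATMSDNLYQRVAT",
                             is_biosynthetic=True,
                             sec_met_raw=("Type: nrps", "Kind: biosynthetic")),
            BiosyntheticGene("orf3", "+", 901, 1100, "MLNNQTWQE",
                             is_biosynthetic=False),
        ]
    if domains is None:
        domains = [
            DomainAnnotation("orf1", "Condensation", 0),
            DomainAnnotation("orf1", "AMP-binding", 1,
                             predictor_calls={"nrpspredictor2": "gly",
                                              "minowa": "gly",
                                              "stachelhaus": "ser"},
                             signature10="DILQLGLIWK"),
            DomainAnnotation("orf1", "PCP", 2),
            DomainAnnotation("orf2", "Condensation", 0),
            DomainAnnotation("orf2", "AMP-binding", 1,
                             predictor_calls={"nrpspredictor2": "thr",
                                              "minowa": "thr"}),
            DomainAnnotation("orf2", "PCP", 2),
        ]
    return ClusterRecord(cluster_id=cluster_id, genome_id=genome_id,
                         bgc_class=bgc_class, contig_id="ctg1",
                         start=1, end=1200, genes=genes, domains=domains)


@pytest.fixture()
def nrps_cluster() -> ClusterRecord:
    return make_cluster()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default synthetic fixture set (two families of five at 0.80
    identity plus one unrelated cluster), written once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    config = default_config(seed=20170818)
    write_fixture_set(config, out)
    return out


@pytest.fixture(scope="session")
def two_family_config() -> FixtureConfig:
    """The study-conditions fixture for network recovery: two families,
    five members each, within-family target identity 0.80."""
    return FixtureConfig(
        seed=42,
        n_genomes=5,
        families=[
            FamilySpec(name="famA", bgc_class="nrps", n_members=5,
                       target_identity=0.80),
            FamilySpec(name="famB", bgc_class="t1pks", n_members=5,
                       target_identity=0.80,
                       domain_template=("KS", "AT", "ACP", "KR", "DH",
                                        "KS", "AT", "ACP", "TE"),
                       substrates=()),
        ],
        unrelated_clusters=0,
    )
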