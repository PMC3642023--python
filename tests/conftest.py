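"""Shared fixtures: the synthetic study (seed 1) and the published-table fixtures."""

from pathlib import Path

import pandas as pd
import pytest

from famprior.cnv import read_cnv_table
from famprior.io import (
    read_frequency_table,
    read_gene_models,
    read_ped,
    read_score_table,
    read_vcf,
)
from famprior.pedigree import Pedigree, PedigreeMember
from famprior.simulate import SimulationConfig, simulate_family

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """The default synthetic family study, seed 1: (manifest, truth)."""
    out = tmp_path_factory.mktemp("sim_seed1")
    return simulate_family(SimulationConfig(seed=1), out_dir=out)


@pytest.fixture(scope="session")
def sim_inputs(sim):
    """Parsed pipeline inputs from the synthetic study."""
    manifest, truth = sim
    freqs, databases = read_frequency_table(manifest["frequencies.tsv"])
    return {
        "manifest": manifest,
        "truth": truth,
        "ped": read_ped(manifest["family.ped"]),
        "genes": read_gene_models(manifest["genes.tsv"]),
        "freqs": freqs,
        "databases": databases,
        "scores": read_score_table(manifest["scores.tsv"]),
        "proband_variants": {
            pid: read_vcf(manifest[f"proband_{pid}.vcf"]) for pid in truth.affected
        },
    }


@pytest.fixture(scope="session")
def array_calls():
    """The 24 array CNV calls of the study pedigree (with expected lengths)."""
    return read_cnv_table(DATA / "array_cnv_calls.tsv")


@pytest.fixture(scope="session")
def array_calls_df():
    return pd.read_csv(DATA / "array_cnv_calls.tsv", sep="\t")


@pytest.fixture(scope="session")
def ibd2_regions_df():
    """The 27 candidate regions where the probands are IBD=2 and unaffected sibs are not."""
    return pd.read_csv(DATA / "candidate_ibd2_regions.tsv", sep="\t")


@pytest.fixture(scope="session")
def study_pedigree():
    """The study family: founders 1 (mother) and 2 (father), children 3-10,
    children 8 and 10 affected, child 9 without DNA."""
    members = [
        PedigreeMember("1", None, None, 2, False),
        PedigreeMember("2", None, None, 1, False),
    ]
    for c in "345679":
        members.append(PedigreeMember(c, "2", "1", 0, False))
    members.append(PedigreeMember("8", "2", "1", 1, True))
    members.append(PedigreeMember("10", "2", "1", 1, True))
    return Pedigree("FAM1", members)
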