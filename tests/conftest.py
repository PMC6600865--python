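import pandas as pd
import pytest
from hypothesis import settings

from tfkit import TFCatalog

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from tfkit.synthetic import (
    make_cisbp_snapshot,
    make_encode_registry,
    make_gwas_table,
    make_hocomoco_snapshot,
    make_scored_track,
    make_tft_collection,
    make_track_set,
)

SEED = 20260923


@pytest.fixture(scope="session")
def cisbp_snapshot(tmp_path_factory):
    d = tmp_path_factory.mktemp("cisbp")
    return make_cisbp_snapshot(d / "cisbp.tsv", seed=SEED, n_genes=40,
                               n_duplicate_rows=10)


@pytest.fixture(scope="session")
def hocomoco_snapshot(tmp_path_factory):
    d = tmp_path_factory.mktemp("hoco")
    return make_hocomoco_snapshot(d / "hocomoco.tsv", seed=SEED, n_rows=20)


@pytest.fixture(scope="session")
def tft_gmt(tmp_path_factory):
    d = tmp_path_factory.mktemp("gmt")
    return make_tft_collection(d / "tft.gmt", seed=SEED, n_sets=12)


@pytest.fixture(scope="session")
def scored_track(tmp_path_factory):
    d = tmp_path_factory.mktemp("track")
    return make_scored_track(d / "sites.bed", seed=SEED, n_sites=1000)


@pytest.fixture(scope="session")
def track_set(tmp_path_factory):
    d = tmp_path_factory.mktemp("tracks")
    return make_track_set(d, seed=SEED, n_files=16, sites_per_file=100)


@pytest.fixture(scope="session")
def encode_fixture(tmp_path_factory):
    d = tmp_path_factory.mktemp("peaks")
    return make_encode_registry(d, seed=SEED)


@pytest.fixture()
def simple_catalog():
    return TFCatalog(
        name="toy",
        native_ids=["a1", "a2", "a3", "a4"],
        hgnc_map=pd.DataFrame(
            {
                "HGNC": ["TP53", "TP53", "YY1", ""],
                "Family_Name": ["p53", "p53-alt", "C2H2 ZF", "?"],
            }
        ),
    )


@pytest.fixture(scope="session")
def gwas_fixture(tmp_path_factory):
    d = tmp_path_factory.mktemp("gwas")
    return make_gwas_table(
        d / "gwas.tsv",
        seed=SEED,
        direct_links={"Trait X": ["TF01", "TF03", "MTF1"]},
        target_links={"Trait Y": {"G0001": 2, "G0002": 1}},
        n_noise=15,
    )
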