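import numpy as np
import pandas as pd
import pytest

from clonefate.counts import NK, ALONE, TP1, TP2
from clonefate.errors import ConfigurationError
from clonefate.extract import count_sample
from clonefate.simulate import (GeneratorConfig, expected_frequencies,
                                generate_library, genotype_config,
                                library_count_matrix, simulate_coculture,
                                synthesize_reads)


def test_config_invariants_enforced():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(fate_weights={f: 0.5 for f in
                                      ("eliminated", "primary_resistant",
                                       "static", "secondary_resistant",
                                       "other")})
    with pytest.raises(ConfigurationError):
        GeneratorConfig(malformed_fraction=1.5)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(dispersion=-1.0)
    with pytest.raises(ConfigurationError):
        GeneratorConfig(n_clones=-1)


def test_empty_library():
    lib, truth = generate_library(GeneratorConfig(n_clones=0))
    assert len(lib) == 0
    assert len(truth.clones) == 0


def test_generate_library_determinism():
    cfg = GeneratorConfig(n_clones=50, seed=3)
    lib1, truth1 = generate_library(cfg)
    lib2, truth2 = generate_library(GeneratorConfig(n_clones=50, seed=3))
    pd.testing.assert_frame_equal(lib1.library_counts, lib2.library_counts)
    pd.testing.assert_frame_equal(truth1.clones, truth2.clones)
    np.testing.assert_array_equal(truth1.lfc_by_well, truth2.lfc_by_well)


def test_barcodes_unique_fixed_length_acgt():
    _, truth = generate_library(GeneratorConfig(n_clones=1000, seed=1))
    barcodes = truth.clones["barcode"]
    assert barcodes.nunique() == 1000
    assert barcodes.str.len().eq(21).all()
    assert barcodes.str.fullmatch("[ACGT]+").all()
    assert truth.clones["founder_abundance"].sum() == pytest.approx(1.0)


def test_impossible_uniqueness_raises():
    with pytest.raises(ConfigurationError):
        generate_library(GeneratorConfig(n_clones=100, barcode_length=3))


def test_secondary_resistant_well_structure():
    """Secondary-resistant clones expand in exactly one well; the others
    carry the eliminated-class effect."""
    cfg = GeneratorConfig(n_clones=800, seed=2)
    _, truth = generate_library(cfg)
    sec = truth.clones["fate"] == "secondary_resistant"
    lfc = truth.lfc_by_well[sec.to_numpy()]
    assert len(lfc) > 0
    assert (np.sum(lfc == cfg.effect_sizes["secondary_resistant"], axis=1)
            == 1).all()
    assert (np.sum(lfc == cfg.effect_sizes["eliminated"], axis=1)
            == cfg.n_wells - 1).all()


def test_fate_frequencies_converge():
    cfg = GeneratorConfig(n_clones=10_000, seed=6)
    _, truth = generate_library(cfg)
    observed = truth.clones["fate"].value_counts(normalize=True)
    for fate, weight in cfg.fate_weights.items():
        got = observed.get(fate, 0.0)
        ci = 3 * np.sqrt(weight * (1 - weight) / cfg.n_clones) + 1e-9
        assert abs(got - weight) <= ci, fate


def test_all_static_means_equal_arms():
    """With every clone static the NK-arm expected frequencies equal the
    tumour-alone frequencies exactly."""
    weights = {"eliminated": 0.0, "primary_resistant": 0.0, "static": 1.0,
               "secondary_resistant": 0.0, "other": 0.0}
    cfg = GeneratorConfig(n_clones=40, fate_weights=weights, seed=4)
    _, truth = generate_library(cfg)
    for tp in (TP1, TP2):
        for well in range(cfg.n_wells):
            np.testing.assert_allclose(
                expected_frequencies(truth, cfg, NK, tp, well),
                expected_frequencies(truth, cfg, ALONE, tp, well))


def test_kill_flag_empties_nk_arm():
    """lfc = -inf is an absorbing state: NK-arm counts are all zero."""
    weights = {"eliminated": 1.0, "primary_resistant": 0.0, "static": 0.0,
               "secondary_resistant": 0.0, "other": 0.0}
    effects = {"eliminated": -np.inf, "primary_resistant": 3.0, "static": 0.0,
               "secondary_resistant": 2.0, "other": 0.0}
    cfg = GeneratorConfig(n_clones=30, fate_weights=weights,
                          effect_sizes=effects, seed=4)
    _, truth = generate_library(cfg)
    cm = simulate_coculture(truth, cfg)
    nk_cols = cm.samples.index[cm.samples["condition"] == NK]
    assert (cm.counts[nk_cols].to_numpy() == 0).all()
    alone_cols = cm.samples.index[cm.samples["condition"] == ALONE]
    assert cm.counts[alone_cols].to_numpy().sum() > 0


def test_coculture_design_shape(small_config, small_counts):
    cfg = small_config
    meta = small_counts.samples
    assert len(meta) == 2 * 2 * cfg.n_wells * cfg.n_techreps
    key = meta[["condition", "timepoint", "well", "techrep"]]
    assert not key.duplicated().any()
    assert small_counts.counts.shape[0] == cfg.n_clones


def test_secondary_expansion_only_at_tp2():
    weights = {"eliminated": 0.0, "primary_resistant": 0.0, "static": 0.5,
               "secondary_resistant": 0.5, "other": 0.0}
    cfg = GeneratorConfig(n_clones=40, fate_weights=weights, seed=8)
    _, truth = generate_library(cfg)
    clone = int((truth.clones["fate"] == "secondary_resistant").idxmax())
    well = int(truth.clones.loc[clone, "expanded_well"])
    f_tp1 = expected_frequencies(truth, cfg, NK, TP1, well)
    f_tp2 = expected_frequencies(truth, cfg, NK, TP2, well)
    founder = truth.clones["founder_abundance"].to_numpy()
    # at TP1 the expanded well still behaves like the eliminated class:
    # the clone loses frequency share to the static background
    assert f_tp1[clone] / founder[clone] < 1.0
    assert f_tp2[clone] > f_tp1[clone]


def test_reads_round_trip_and_geometry(tmp_path, small_config, small_truth,
                                       small_counts):
    """With no malformed reads the FASTQ round trip reproduces the count
    matrix exactly, every read is read_length nt, and intact reads carry
    both anchors."""
    cfg = GeneratorConfig(**{**small_config.__dict__, "malformed_fraction": 0.0})
    _, truth = small_truth
    paths = synthesize_reads(small_counts, truth, cfg, tmp_path)
    sid = small_counts.counts.columns[0]
    res = count_sample(paths[sid], cfg.head, cfg.tail, cfg.barcode_length)
    expected = small_counts.counts[sid]
    assert res.total_reads == expected.sum()          # conservation
    assert res.discard_fraction == 0.0
    recovered = pd.Series(res.raw_counts).reindex(expected.index, fill_value=0)
    pd.testing.assert_series_equal(recovered.astype("int64"),
                                   expected, check_names=False)
    with open(paths[sid]) as fh:
        lines = fh.read().splitlines()
    seqs = lines[1::4]
    assert all(len(s) == cfg.read_length for s in seqs)
    assert all(cfg.head in s and cfg.tail in s for s in seqs)


def test_reads_deterministic_bytes(tmp_path, small_config, small_truth,
                                   small_counts):
    _, truth = small_truth
    p1 = synthesize_reads(small_counts, truth, small_config, tmp_path / "a")
    p2 = synthesize_reads(small_counts, truth, small_config, tmp_path / "b")
    sid = small_counts.counts.columns[3]
    assert p1[sid].read_bytes() == p2[sid].read_bytes()


def test_read_length_too_short_raises(tmp_path, small_truth, small_counts):
    lib, truth = small_truth
    cfg = GeneratorConfig(n_clones=150, read_length=40)
    with pytest.raises(ConfigurationError):
        synthesize_reads(small_counts, truth, cfg, tmp_path)


def test_unknown_barcodes_rejected(tmp_path, small_config, small_truth):
    _, truth = small_truth
    rogue = small_config
    counts = pd.DataFrame({"s": [3]}, index=["T" * 21])
    meta = pd.DataFrame([dict(sample_id="s", cell_line="A",
                              condition="alone", nk_genotype="none",
                              timepoint="TP1", well=1, techrep=1)]
                        ).set_index("sample_id")
    from clonefate.counts import CountMatrix
    cm = CountMatrix(counts, meta)
    if "T" * 21 in set(truth.barcodes):   # vanishingly unlikely
        pytest.skip("random collision with truth barcode")
    with pytest.raises(ConfigurationError):
        synthesize_reads(cm, truth, rogue, tmp_path)


def test_library_counts_cover_barcodes(small_config, small_truth):
    lib, truth = small_truth
    assert set(lib.library_counts.index) == set(truth.barcodes)
    assert lib.n_library_samples == small_config.n_library_samples
    cm = library_count_matrix(lib, small_config)
    assert (cm.samples["condition"] == "library").all()


def test_genotype_presets_shift_elimination():
    base = GeneratorConfig()
    prf1 = genotype_config(base, "Prf1KO")
    ifng = genotype_config(base, "IfngKO")
    assert prf1.fate_weights["eliminated"] == pytest.approx(0.8 * 0.585)
    assert ifng.fate_weights["eliminated"] < prf1.fate_weights["eliminated"]
    assert sum(ifng.fate_weights.values()) == pytest.approx(1.0)
    with pytest.raises(ConfigurationError):
        genotype_config(base, "Ncr1KO")
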