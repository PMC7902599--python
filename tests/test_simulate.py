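import filecmp
import json

import numpy as np
import pytest

from pollenx import expression, gtfio
from pollenx.simulate import GroundTruth, SimConfig, SizingError, simulate_run


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(class_mix={"short": 0.5, "lncRNA": 0.5, "lincRNA": 0.0,
                             "orf_coding": 0.1}).validate()
    with pytest.raises(ValueError):
        SimConfig(n_novel_loci=0).validate()
    with pytest.raises(ValueError):
        SimConfig(nb_dispersion=0.0).validate()
    with pytest.raises(ValueError):
        SimConfig(mirna_length=10).validate()
    SimConfig().validate()


def test_sizing_error_when_genome_too_small():
    with pytest.raises(SizingError):
        simulate_run(SimConfig(seed=0, chrom_length=20_000, n_novel_loci=100))


def test_same_seed_same_bytes(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    cfg = SimConfig(seed=12, n_novel_loci=25)
    simulate_run(cfg, outdir=a)
    simulate_run(SimConfig(seed=12, n_novel_loci=25), outdir=b)
    files = sorted(p.name for p in a.iterdir())
    assert files == sorted(p.name for p in b.iterdir())
    for name in files:
        assert filecmp.cmp(a / name, b / name, shallow=False), name


def test_different_seed_differs(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_run(SimConfig(seed=1, n_novel_loci=25), outdir=a)
    simulate_run(SimConfig(seed=2, n_novel_loci=25), outdir=b)
    assert not filecmp.cmp(a / "genome.fa", b / "genome.fa", shallow=False)


def test_truth_json_roundtrip(cohort_dir, cohort_truth):
    gt = cohort_truth
    assert len(gt.loci) == 60
    back = GroundTruth.from_json(cohort_dir / "ground_truth.json")
    assert set(back.loci) == set(gt.loci)
    some = next(iter(gt.loci.values()))
    assert some.biotype in ("short", "lncRNA", "lincRNA", "orf_coding")


def test_planted_truth_internally_consistent(cohort_truth):
    cfg = cohort_truth.config
    for t in cohort_truth.loci.values():
        # PSX implies PEX somewhere and sporophytic silence
        if t.psx:
            assert any(t.pex.values())
            for ds in cfg.sporophytic_datasets:
                assert max(t.mean_rpm[ds].values()) < 1.0
        # hPEX implies PEX per dataset
        for ds, h in t.hpex.items():
            if h:
                assert t.pex[ds]
        # planted means match the planted pex/hpex flags exactly
        for ds in cfg.pollen_datasets:
            top = max(t.mean_rpm[ds].values())
            assert t.pex[ds] == (top > 1.0)
            assert t.hpex[ds] == (top > 10.0)
        # translation requires a planted ORF
        if t.translated:
            assert t.biotype == "orf_coding" and t.orf_frame is not None


def test_multi_isoform_count_matches_fraction(cohort_truth):
    cfg = cohort_truth.config
    n_multi = sum(len(t.tcons) >= 2 for t in cohort_truth.loci.values())
    assert n_multi == round(cfg.multi_isoform_fraction * cfg.n_novel_loci)


def test_study_size_defaults():
    cfg = SimConfig()
    assert cfg.n_novel_loci == 312
    assert round(cfg.multi_isoform_fraction * 312) == 41
    assert round(cfg.recent_fraction * 312) == 246
    assert cfg.datasets == ["MP_HS", "MP_HotCold", "GP_HS", "CL_HS"]


def test_noncoding_loci_have_no_long_orf(cohort_dir, cohort_truth):
    transcripts = {t.tcons_id: t for t in gtfio.read_transcript_gtf(cohort_dir / "transcripts.gtf")}
    genome = gtfio.read_genome(cohort_dir / "genome.fa")
    from pollenx.orf import find_orfs, longest_orf_aa
    for truth in cohort_truth.loci.values():
        t = transcripts[truth.primary_tcons]
        seq = gtfio.spliced_sequence(t, genome)
        mode = "both" if t.strand == "." else "forward"
        aa = longest_orf_aa(find_orfs(seq, strand_mode=mode))
        if truth.biotype == "orf_coding":
            assert aa >= 100
        else:
            assert aa < 100, truth.xloc_id


def test_counts_match_sample_sheet(cohort_dir):
    import pandas as pd
    counts = pd.read_csv(cohort_dir / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(cohort_dir / "samples.tsv", sep="\t")
    study = expression.ExpressionStudy(counts, samples)  # validates the pairing
    assert set(study.pollen_datasets()) == {"MP_HS", "MP_HotCold", "GP_HS"}
    assert study.sporophytic_datasets() == ["CL_HS"]
    assert (counts.to_numpy() >= 0).all()
    assert len(counts) == 60


def test_sampled_counts_near_planted_means(cohort_dir, cohort_truth):
    """Sampled mean RPM stays on the right side of every calling threshold."""
    import pandas as pd
    counts = pd.read_csv(cohort_dir / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(cohort_dir / "samples.tsv", sep="\t")
    study = expression.ExpressionStudy(counts, samples)
    mean = expression.condition_mean_rpm(study)
    pollen = set(cohort_truth.config.pollen_datasets)
    for x, t in cohort_truth.loci.items():
        for ds, conds in t.mean_rpm.items():
            # calls use the best condition of a dataset; planted levels
            # guarantee threshold sidedness of that maximum only, and the
            # 10 RPM (hPEX) threshold applies to pollen datasets alone
            planted = max(conds.values())
            got = mean.loc[x, ds].max()
            thresholds = (1.0, 10.0) if ds in pollen else (1.0,)
            for thr in thresholds:
                assert (got > thr) == (planted > thr), (x, ds, got, planted)
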