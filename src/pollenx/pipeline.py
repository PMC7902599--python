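"""End-to-end locus characterization: one record per intergenic locus.

``run_pipeline`` wires the stage modules together over a directory of
inputs (transcript models, two reference annotations, a TE annotation,
genome, count matrices, homology tables, miRNA sequences and P-site
tracks) and produces a per-locus table — novelty, biotype, expression and
specificity flags, differential expression per dataset, phylostratum,
protein-homology bin, miRNA target hits and translation call — plus a
summary of the partition counts and cross-dataset overlaps.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression, gtfio, mirna, orf, phylostrata, ribo
from .intervals import (
    AnnotationSet,
    TranscriptModel,
    classify_novelty,
    distance_to_nearest_gene,
    group_into_loci,
    te_overlap,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every numeric threshold of the characterization, in one place.

    Defaults are the operational thresholds of the pollen heat-stress
    cohort this package models.
    """

    min_count: int = 10
    rpm_pex: float = 1.0
    rpm_hpex: float = 10.0
    rpm_present: float = 0.05
    lfc_min: float = 1.0
    padj_max: float = 0.05
    linc_distance: int = 500
    orf_min_aa: int = 100
    short_max_nt: int = 200
    evalue_phylo: float = 1e-5
    evalue_blastx: float = 1e-7
    expectation_max: float = 3.0
    mirna_max_gaps: int = 1
    min_pf: int = 5
    rpf_rpm_min: float = 1.0
    pf_min_count: int = 1
    focal_species: str = "Arabidopsis thaliana"

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def with_overrides(self, **kwargs) -> "RunConfig":
        known = {f.name for f in fields(self)}
        bad = set(kwargs) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        merged = {f.name: getattr(self, f.name) for f in fields(self)}
        merged.update(kwargs)
        cfg = RunConfig(**merged)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    records: pd.DataFrame  # one row per included locus
    excluded: list[str]  # loci removed as already annotated in the older reference
    summary: dict
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


INPUT_FILES = {
    "transcripts": "transcripts.gtf",
    "genome": "genome.fa",
    "tair": "reference_tair.gff3",
    "araport": "reference_araport.gff3",
    "te": "te.gff3",
    "counts": "counts.tsv",
    "samples": "samples.tsv",
    "phylo_hits": "phylo_hits.tsv",
    "lineages": "lineages.tsv",
    "blastx_hits": "blastx_hits.tsv",
    "mirnas": "mirnas.fa",
    "psite_tracks": "psite_tracks.tsv",
}


def _require(indir: Path, key: str) -> Path:
    p = indir / INPUT_FILES[key]
    if not p.exists():
        raise FileNotFoundError(f"missing pipeline input: {p}")
    return p


def classify_loci(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    tair: AnnotationSet,
    araport: AnnotationSet,
    te_set: AnnotationSet,
    config: RunConfig,
) -> pd.DataFrame:
    """Group transcripts into loci and classify novelty and biotype.

    The locus biotype is that of its longest (by spliced length)
    transcript; known-strand transcripts are ORF-scanned on their sense
    strand only, unknown-strand ones on both.
    """
    group_into_loci(transcripts)
    by_locus: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_locus.setdefault(t.xloc_id, []).append(t)

    coding_genes = araport.subset({"protein_coding"})
    rows = []
    for xloc in sorted(by_locus):
        ts = by_locus[xloc]
        exons = [e for t in ts for e in t.exons]
        novelty = classify_novelty(exons, tair, araport)
        distance = distance_to_nearest_gene(exons, coding_genes)
        te_flag = te_overlap(exons, te_set)
        longest = max(ts, key=lambda t: (t.spliced_length, t.tcons_id))
        seq = gtfio.spliced_sequence(longest, genome)
        mode = "both" if longest.strand == "." else "forward"
        orfs = orf.find_orfs(seq, strand_mode=mode)
        call = orf.classify_biotype(
            longest.spliced_length,
            orfs,
            distance,
            te_flag,
            short_max_nt=config.short_max_nt,
            orf_min_aa=config.orf_min_aa,
            linc_min_distance=config.linc_distance,
        )
        rows.append(
            {
                "locus": xloc,
                "tcons": ",".join(sorted(t.tcons_id for t in ts)),
                "n_isoforms": len(ts),
                "primary_tcons": longest.tcons_id,
                "strand": longest.strand,
                "novelty": novelty,
                "biotype": call.biotype,
                "spliced_length": call.spliced_length,
                "longest_orf_aa": call.longest_orf_aa,
                "distance_to_gene": distance,
                "te_overlap": te_flag,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def run_pipeline(indir: str | Path, config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    config.validate()
    indir = Path(indir)

    transcripts = gtfio.read_transcript_gtf(_require(indir, "transcripts"))
    ids = [t.tcons_id for t in transcripts]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript identifiers in input: {dupes[:5]}")
    genome = gtfio.read_genome(_require(indir, "genome"))
    tair = gtfio.read_annotation(_require(indir, "tair"))
    araport = gtfio.read_annotation(_require(indir, "araport"))
    te_set = gtfio.read_annotation(_require(indir, "te"), default_biotype="TE")
    log.info(
        "classify: %d transcripts, %d older / %d newer annotation features, "
        "%d TE features (short<%d nt, ORF>=%d aa, lincRNA>=%d bp)",
        len(transcripts), len(tair), len(araport), len(te_set),
        config.short_max_nt, config.orf_min_aa, config.linc_distance,
    )

    records = classify_loci(transcripts, genome, tair, araport, te_set, config)
    excluded = list(records.index[records.novelty == "known"])
    records = records[records.novelty != "known"].copy()
    loci = list(records.index)
    log.info("classify: %d loci kept, %d known loci excluded", len(loci), len(excluded))

    # ---- expression: RPM thresholds, specificity, per-dataset DE
    counts = pd.read_csv(_require(indir, "counts"), sep="\t", index_col=0)
    samples = pd.read_csv(_require(indir, "samples"), sep="\t")
    study = expression.ExpressionStudy(counts, samples)
    log.info(
        "expression: %d loci x %d samples over datasets %s "
        "(PEX>%g, hPEX>%g, present>=%g RPM; DEX |LFC|>=%g, padj<%g, min count %d)",
        len(counts), len(counts.columns), study.datasets,
        config.rpm_pex, config.rpm_hpex, config.rpm_present,
        config.lfc_min, config.padj_max, config.min_count,
    )
    mean_rpm = expression.condition_mean_rpm(study).reindex(loci).fillna(0.0)
    pollen_ds = study.pollen_datasets()
    sporo_ds = study.sporophytic_datasets()
    spec_call = expression.call_specificity(
        mean_rpm, pollen_ds, sporo_ds,
        rpm_pex=config.rpm_pex, rpm_hpex=config.rpm_hpex, rpm_present=config.rpm_present,
    )
    for ds in study.datasets:
        for cond in ("control", "HS"):
            if (ds, cond) in mean_rpm.columns:
                records[f"rpm_{ds}_{cond}"] = mean_rpm[(ds, cond)]
    records = records.join(spec_call.table)

    de_tables: dict[str, pd.DataFrame] = {}
    for ds in study.datasets:
        sheet = study.dataset_samples(ds)
        if set(sheet.condition) != {expression.CONTROL, expression.TREATED}:
            continue
        res = expression.nb_wald_test(
            study, ds, min_count=config.min_count,
            lfc_min=config.lfc_min, padj_max=config.padj_max,
        )
        tab = res.table.reindex(loci)
        de_tables[ds] = tab
        log.info(
            "expression: %s tested %d of %d loci (low-count filter), %d DEX",
            ds, len(res.table), len(loci), int(res.table.dex.sum()),
        )
        records[f"lfc_{ds}"] = tab.lfc
        records[f"padj_{ds}"] = tab.padj
        records[f"dex_{ds}"] = tab.dex.eq(True).to_numpy()

    # ---- phylostratigraphy
    lineages = phylostrata.read_lineage_file(_require(indir, "lineages"))
    if config.focal_species not in lineages:
        raise KeyError(f"focal species {config.focal_species!r} not in lineage file")
    focal = lineages[config.focal_species]
    hit_table = phylostrata.read_hit_table(_require(indir, "phylo_hits"))
    strata = phylostrata.assign_all(
        hit_table, lineages, focal, loci, evalue_max=config.evalue_phylo
    )
    records["stratum"] = strata.stratum
    records["n_phylo_hits"] = strata.n_hits
    log.info(
        "phylostrata: %d hits over %d loci, %d loci with passing hits (E<=%g)",
        len(hit_table), len(loci), int((strata.n_hits > 0).sum()), config.evalue_phylo,
    )

    # ---- protein homology bins
    hom = orf.parse_homology_table(
        _require(indir, "blastx_hits"), evalue_max=config.evalue_blastx
    )
    records["homology_bin"] = [
        hom.get(x, orf.NO_HOMOLOGY).bin for x in records.index
    ]
    log.info(
        "homology: %d loci with a passing best hit of %d loci (E<=%g)",
        sum(x in hom for x in records.index), len(loci), config.evalue_blastx,
    )

    # ---- miRNA targets (scan the longest transcript of each locus)
    mirnas = gtfio.read_genome(_require(indir, "mirnas"))
    by_tcons = {t.tcons_id: t for t in transcripts}
    locus_seqs = {
        x: gtfio.spliced_sequence(by_tcons[records.primary_tcons[x]], genome)
        for x in records.index
    }
    hits = mirna.find_targets(
        mirnas, locus_seqs,
        expectation_max=config.expectation_max, max_gaps=config.mirna_max_gaps,
    )
    hits_by_locus: dict[str, list[mirna.TargetHit]] = {}
    for h in hits:
        hits_by_locus.setdefault(h.locus, []).append(h)
    records["n_mirna_hits"] = [len(hits_by_locus.get(x, [])) for x in records.index]
    records["mirna_hits"] = [
        ";".join(
            f"{h.mirna_id}@{h.start}:{h.expectation:g}:{h.mode}"
            for h in hits_by_locus.get(x, [])
        )
        for x in records.index
    ]
    log.info(
        "mirna: %d miRNAs x %d loci, %d sites in %d target loci "
        "(expectation<=%g, max %d bulge)",
        len(mirnas), len(locus_seqs), len(hits), len(hits_by_locus),
        config.expectation_max, config.mirna_max_gaps,
    )

    # ---- translation calls from P-site tracks
    track_path = indir / INPUT_FILES["psite_tracks"]
    tracks = ribo.read_tracks(track_path) if track_path.exists() else {}
    tids = set().union(*(set(t) for t in tracks.values())) if tracks else set()
    calls: dict[str, ribo.TranslationCall] = {}
    for tid in tids:
        per_cond = {c: tracks[c][tid] for c in tracks if tid in tracks[c]}
        calls[tid] = ribo.call_translation(
            per_cond, min_pf=config.min_pf,
            rpf_rpm_min=config.rpf_rpm_min, pf_min_count=config.pf_min_count,
        )

    def locus_call(x: str) -> ribo.TranslationCall | None:
        got = [calls[t] for t in records.tcons[x].split(",") if t in calls]
        if not got:
            return None
        return max(got, key=lambda c: (c.translated, c.considered, max(c.pf_counts)))

    lc = {x: locus_call(x) for x in records.index}
    records["rpf_considered"] = [bool(lc[x] and lc[x].considered) for x in records.index]
    records["translated"] = [bool(lc[x] and lc[x].translated) for x in records.index]
    records["multi_frame"] = [bool(lc[x] and lc[x].multi_frame) for x in records.index]
    records["dominant_frame"] = [
        lc[x].dominant_frame if lc[x] and lc[x].translated else None
        for x in records.index
    ]

    log.info(
        "ribo: %d tracked transcripts, %d loci considered, %d translated "
        "(RPM>=%g, PF count>=%d, min PF positions %d)",
        len(tids), int(records.rpf_considered.sum()), int(records.translated.sum()),
        config.rpf_rpm_min, config.pf_min_count, config.min_pf,
    )

    summary = summarize(records, pollen_ds, excluded)
    return PipelineResult(
        records=records, excluded=excluded, summary=summary, de_tables=de_tables
    )


def summarize(records: pd.DataFrame, pollen_datasets: list[str], excluded: list[str]) -> dict:
    """Partition counts and cross-dataset DEX overlaps for a record table."""
    dex_sets = {
        ds: set(records.index[records[f"dex_{ds}"]])
        for ds in pollen_datasets
        if f"dex_{ds}" in records.columns
    }
    return {
        "n_loci": int(len(records)),
        "n_excluded_known": len(excluded),
        "n_multi_isoform": int((records.n_isoforms >= 2).sum()),
        "novelty": records.novelty.value_counts().to_dict(),
        "biotype": records.biotype.value_counts().to_dict(),
        "n_lncRNA_total": int(records.biotype.isin(["lncRNA", "lincRNA"]).sum()),
        "pex_per_dataset": {
            ds: int(records[f"pex_{ds}"].sum())
            for ds in pollen_datasets if f"pex_{ds}" in records.columns
        },
        "hpex_per_dataset": {
            ds: int(records[f"hpex_{ds}"].sum())
            for ds in pollen_datasets if f"hpex_{ds}" in records.columns
        },
        "n_pex": int(records.pex.sum()),
        "n_psx": int(records.psx.sum()),
        "dex_per_dataset": {ds: len(s) for ds, s in dex_sets.items()},
        "n_dex_any": len(set().union(*dex_sets.values())) if dex_sets else 0,
        "dex_overlaps": summarize_overlaps(dex_sets),
        "strata": records.stratum.value_counts().to_dict(),
        "homology_bins": records.homology_bin.value_counts().to_dict(),
        "n_mirna_targets": int((records.n_mirna_hits > 0).sum()),
        "n_rpf_considered": int(records.rpf_considered.sum()),
        "n_translated": int(records.translated.sum()),
    }


def summarize_overlaps(sets: dict[str, set]) -> dict[str, int]:
    """Exclusive region counts of the k-set Venn partition (2^k - 1 regions).

    Keys are '+'-joined member names; region counts sum to |union|.
    """
    names = sorted(sets)
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if (
                len(combo) < len(names)
            ) else set()
            out["+".join(combo)] = len(inside - outside)
    return out


# ---------------------------------------------------------------- recount

#: canonical column names ``recount`` expects; a schema file maps actual
#: table headers onto these
RECOUNT_BASE_COLUMNS = [
    "locus", "n_isoforms", "novelty", "spliced_length", "longest_orf_aa",
    "distance_to_gene", "te_overlap",
]


def recount_from_supplementary(
    table: pd.DataFrame,
    config: RunConfig | None = None,
    schema: dict[str, str] | None = None,
) -> dict:
    """Headline cohort counts recomputed from a per-locus characterization table.

    The table needs the :data:`RECOUNT_BASE_COLUMNS` (possibly renamed via
    ``schema``: canonical name -> actual column) and may carry expression
    columns ``rpm_<dataset>_<condition>``, ``lfc_<dataset>`` and
    ``padj_<dataset>``; the classification and threshold rules of this
    package are applied to those columns and the resulting counts returned.
    """
    config = config or RunConfig()
    if schema:
        table = table.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in RECOUNT_BASE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"recount table lacks columns {missing}")
    t = table.set_index("locus") if table.index.name != "locus" else table

    biotypes = []
    for _, row in t.iterrows():
        call = orf.classify_biotype(
            int(row.spliced_length),
            [],
            int(row.distance_to_gene),
            bool(row.te_overlap),
            short_max_nt=config.short_max_nt,
            orf_min_aa=config.orf_min_aa,
            linc_min_distance=config.linc_distance,
        )
        # classify_biotype rescans ORFs from sequence; in table form the
        # longest ORF is already a column, so apply the length rule directly
        if (
            int(row.spliced_length) >= config.short_max_nt
            and int(row.longest_orf_aa) >= config.orf_min_aa
        ):
            biotypes.append("orf_coding")
        else:
            biotypes.append(call.biotype)
    bio = pd.Series(biotypes, index=t.index)

    out = {
        "n_loci": int(t.index.nunique()),
        "n_multi_isoform": int((t.n_isoforms >= 2).sum()),
        "n_novel": int((t.novelty == "novel").sum()),
        "n_recent": int((t.novelty == "recent").sum()),
        "n_lncRNA_total": int(bio.isin(["lncRNA", "lincRNA"]).sum()),
        "n_lincRNA": int((bio == "lincRNA").sum()),
        "n_orf_coding": int((bio == "orf_coding").sum()),
        "n_short": int((bio == "short").sum()),
    }
    rpm_cols = [c for c in t.columns if c.startswith("rpm_")]
    datasets = sorted({c[4:].rsplit("_", 1)[0] for c in rpm_cols})
    for ds in datasets:
        cols = [c for c in rpm_cols if c[4:].rsplit("_", 1)[0] == ds]
        block = t[cols].astype(float)
        out[f"n_pex_{ds}"] = int((block > config.rpm_pex).any(axis=1).sum())
        out[f"n_hpex_{ds}"] = int((block > config.rpm_hpex).any(axis=1).sum())
        if f"lfc_{ds}" in t.columns and f"padj_{ds}" in t.columns:
            dex = expression.call_dex(
                t[f"lfc_{ds}"].astype(float), t[f"padj_{ds}"].astype(float),
                lfc_min=config.lfc_min, padj_max=config.padj_max,
            )
            out[f"n_dex_{ds}"] = int(pd.Series(dex).sum())
    return out


def write_result(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "xloc_records.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(_jsonable(result.summary), indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
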