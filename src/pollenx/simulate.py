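"""Synthetic pipeline inputs with known ground truth.

The generator emulates the study design this package models: three pollen
RNA-seq datasets (two from maturing pollen, one from germinating pollen
with matching ribosome profiling) plus one cauline-leaf dataset, each with
control and heat-stress conditions in three replicates.  Loci are planted
with known biotype (short / lncRNA / lincRNA / ORF-coding), novelty
against two reference annotations, expression level and fold change,
phylostratum, protein-homology bin, miRNA target sites and translation
status, so the full pipeline can be checked for exact recovery.

All randomness flows through one NumPy generator seeded from the config;
stages draw in a fixed order (genome, annotation, transcripts, counts,
P-site tracks, homology, miRNAs) so outputs are byte-reproducible.

Planted expression levels sit well away from the calling thresholds
(1, 10 and 0.05 RPM) so that threshold calls on sampled counts equal the
planted truth with overwhelming probability at the default library sizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gtfio
from .intervals import AnnotationSet, GenomicInterval, TranscriptModel, group_into_loci
from .orf import find_orfs
from .phylostrata import Lineage

CLASSES = ("short", "lncRNA", "lincRNA", "orf_coding")

#: focal species lineage, root first
FOCAL_LINEAGE = Lineage(
    (
        "cellular organisms", "Viridiplantae", "Streptophyta", "Magnoliopsida",
        "Eudicotyledons", "Brassicales", "Brassicaceae", "Camelineae",
        "Arabidopsis", "Arabidopsis thaliana",
    )
)

#: small fixed taxonomy; keys are hit taxa, values root-to-tip lineages
TAXA_LINEAGES: dict[str, Lineage] = {
    "Arabidopsis lyrata": Lineage(FOCAL_LINEAGE.nodes[:-1] + ("Arabidopsis lyrata",)),
    "Capsella rubella": Lineage(
        FOCAL_LINEAGE.nodes[:-2] + ("Capsella", "Capsella rubella")
    ),
    "Brassica rapa": Lineage(
        FOCAL_LINEAGE.nodes[:-3] + ("Brassiceae", "Brassica", "Brassica rapa")
    ),
    "Solanum lycopersicum": Lineage(
        FOCAL_LINEAGE.nodes[:5] + ("Solanales", "Solanum", "Solanum lycopersicum")
    ),
    "Oryza sativa": Lineage(
        FOCAL_LINEAGE.nodes[:4] + ("Liliopsida", "Poaceae", "Oryza", "Oryza sativa")
    ),
}

#: taxon whose LCA with the focal species is exactly this node
NODE_TO_TAXON = {
    "Arabidopsis": "Arabidopsis lyrata",
    "Camelineae": "Capsella rubella",
    "Brassicaceae": "Brassica rapa",
    "Eudicotyledons": "Solanum lycopersicum",
    "Magnoliopsida": "Oryza sativa",
}

#: ordered from species toward the root; taxa younger than a node
_NODE_ORDER = [
    "Arabidopsis thaliana", "Arabidopsis", "Camelineae", "Brassicaceae",
    "Eudicotyledons", "Magnoliopsida",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    The defaults mirror the cohort this package was built around: 312
    intergenic loci seen in three pollen heat-stress experiments and one
    leaf experiment, three replicates per condition, with most loci
    noncoding, pollen-specific and recently evolved.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_reference_genes: int = 150
    n_te: int = 80
    n_novel_loci: int = 312
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "short": 0.01, "lncRNA": 0.78, "lincRNA": 0.12, "orf_coding": 0.09
        }
    )
    multi_isoform_fraction: float = 41 / 312
    recent_fraction: float = 246 / 312  # loci later annotated in the newer reference
    n_known_decoys: int = 0  # transcripts overlapping the older annotation (excluded)
    n_datasets: int = 4  # pollen datasets plus one final sporophytic dataset
    replicates_per_condition: int = 3
    library_size: int = 2_000_000
    nb_dispersion: float = 0.05
    de_fraction: float = 0.2
    planted_lfc: float = 2.0
    psx_fraction: float = 230 / 312
    hpex_fraction: float = 0.85
    germinated_expressed_fraction: float = 61 / 312  # loci detectable in dataset 3
    stratum_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Arabidopsis thaliana": 0.577, "Arabidopsis": 0.18, "Camelineae": 0.05,
            "Brassicaceae": 0.164, "Eudicotyledons": 0.016, "Magnoliopsida": 0.013,
        }
    )
    homology_fraction: float = 116 / 312  # loci with a passing protein-homology hit
    mirna_target_fraction: float = 50 / 312
    n_mirnas: int = 8
    mirna_length: int = 21
    translated_fraction: float = 0.8  # of ORF-coding loci detectable in dataset 3
    psite_signal_rate: float = 2.0
    psite_noise_rate: float = 0.02
    rpf_library_size: int = 2_000_000

    def validate(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if set(self.class_mix) != set(CLASSES):
            raise ValueError(f"class_mix must cover exactly {CLASSES}")
        if abs(sum(self.stratum_mix.values()) - 1.0) > 1e-9:
            raise ValueError("stratum_mix proportions must sum to 1")
        for name in ("n_chromosomes", "chrom_length", "n_novel_loci",
                     "replicates_per_condition", "library_size", "rpf_library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_reference_genes", "n_te", "n_known_decoys", "n_mirnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not np.isfinite(self.planted_lfc):
            raise ValueError("planted_lfc must be finite")
        if self.n_datasets < 2:
            raise ValueError("need at least one pollen and one sporophytic dataset")
        if self.mirna_length < 15:
            raise ValueError("mirna_length must be >= 15 nt")

    @property
    def pollen_datasets(self) -> list[str]:
        base = ["MP_HS", "MP_HotCold", "GP_HS"]
        n = self.n_datasets - 1
        return (base + [f"pollen_{i}" for i in range(4, n + 1)])[:n]

    @property
    def sporophytic_datasets(self) -> list[str]:
        return ["CL_HS"]

    @property
    def datasets(self) -> list[str]:
        return self.pollen_datasets + self.sporophytic_datasets


@dataclass
class LocusTruth:
    """Ground truth for one planted locus (one record per locus)."""

    xloc_id: str
    tcons: list[str]
    primary_tcons: str
    biotype: str
    novelty: str  # novel | recent | known
    strand: str
    te_overlap: bool
    linc_distance_ok: bool
    mean_rpm: dict[str, dict[str, float]]  # dataset -> condition -> true mean RPM
    lfc: dict[str, float]
    dex: dict[str, bool]
    pex: dict[str, bool]
    hpex: dict[str, bool]
    present: dict[str, bool]
    psx: bool
    stratum: str
    homology_bin: str
    considered_rpf: bool
    translated: bool
    orf_frame: int | None
    mirna_sites: list[dict]


@dataclass
class GroundTruth:
    config: SimConfig
    loci: dict[str, LocusTruth]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "loci": {k: dataclasses.asdict(v) for k, v in self.loci.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cfg = SimConfig(**payload["config"])
        loci = {k: LocusTruth(**v) for k, v in payload["loci"].items()}
        return cls(config=cfg, loci=loci)


class SizingError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOP_SET = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_SET
]
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class _Cursor:
    """Sequential feature placement along chromosomes."""

    def __init__(self, chroms: list[str], length: int):
        self.pos = {c: 1000 for c in chroms}
        self.length = length

    def place(self, chrom: str, size: int, gap: int) -> GenomicInterval:
        start = self.pos[chrom] + gap
        end = start + size
        if end > self.length - 1000:
            raise SizingError(
                f"{chrom}: cannot place a {size} bp feature at {start}; "
                f"increase chrom_length or reduce feature counts"
            )
        self.pos[chrom] = end
        return GenomicInterval(chrom, start, end)


class Simulation:
    """Stateful generator; run the ``generate_*`` stages in order (or
    :func:`simulate_run` end to end)."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.chroms = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
        self.genome_arrays: dict[str, np.ndarray] = {}
        self.tair_features: list[tuple[GenomicInterval, str]] = []
        self.araport_extra: list[tuple[GenomicInterval, str]] = []
        self.te_features: list[tuple[GenomicInterval, str]] = []
        self.transcripts: list[TranscriptModel] = []
        self.truth: dict[str, LocusTruth] = {}
        self._locus_plans: list[dict] = []
        self._cursor = _Cursor(self.chroms, config.chrom_length)
        self._genes_placed = 0
        # tabular outputs, filled by later stages
        self.counts: pd.DataFrame | None = None
        self.samples: pd.DataFrame | None = None
        self.tracks: dict[str, dict] = {}
        self.track_lengths: dict[str, int] = {}
        self.phylo_hits: pd.DataFrame | None = None
        self.blastx_hits: pd.DataFrame | None = None
        self.mirnas: dict[str, str] = {}

    # ------------------------------------------------------------ genome

    def generate_genome_and_annotation(self) -> None:
        cfg = self.config
        for chrom in self.chroms:
            self.genome_arrays[chrom] = self.rng.choice(BASES, size=cfg.chrom_length)
        self._plan_loci()
        self._place_features()
        # leftover reference genes and TEs go into the remaining space
        extra_genes = max(0, cfg.n_reference_genes - self._genes_placed)
        for i in range(extra_genes):
            chrom = self.chroms[i % len(self.chroms)]
            iv = self._cursor.place(chrom, int(self.rng.integers(800, 2500)), gap=700)
            self.tair_features.append((self._stranded(iv), "protein_coding"))
            self._genes_placed += 1
        placed_te = sum(1 for _ in self.te_features)
        for i in range(max(0, cfg.n_te - placed_te)):
            chrom = self.chroms[i % len(self.chroms)]
            iv = self._cursor.place(chrom, int(self.rng.integers(300, 1200)), gap=700)
            self.te_features.append((self._stranded(iv), "TE"))

    def _stranded(self, iv: GenomicInterval) -> GenomicInterval:
        strand = "+" if self.rng.random() < 0.5 else "-"
        return GenomicInterval(iv.chrom, iv.start, iv.end, strand)

    def _plan_loci(self) -> None:
        """Assign class, novelty and context flags before placement."""
        cfg = self.config
        rng = self.rng
        classes = list(cfg.class_mix)
        probs = np.array([cfg.class_mix[c] for c in classes])
        n = cfg.n_novel_loci
        drawn = rng.choice(len(classes), size=n, p=probs)
        n_multi = int(round(cfg.multi_isoform_fraction * n))
        multi = set(rng.choice(n, size=min(n_multi, n), replace=False))
        n_recent = int(round(cfg.recent_fraction * n))
        recent = set(rng.choice(n, size=min(n_recent, n), replace=False))
        for i in range(n):
            cls = classes[drawn[i]]
            if cls == "orf_coding":
                strand = "+"  # coding strand resolved by the stranded libraries
            else:
                strand = rng.choice(["+", "-", "."], p=[0.25, 0.25, 0.5])
            # how a non-linc lncRNA fails the lincRNA criteria
            violation = None
            if cls == "lncRNA":
                violation = "near_gene" if rng.random() < 0.5 else "te"
            self._locus_plans.append(
                {
                    "class": cls,
                    "strand": str(strand),
                    "multi": i in multi,
                    "novelty": "recent" if i in recent else "novel",
                    "violation": violation,
                }
            )

    def _place_features(self) -> None:
        """Lay out genes, TEs and novel-locus footprints chromosome by
        chromosome, honouring each class's distance/TE constraints."""
        cfg = self.config
        rng = self.rng
        for i, plan in enumerate(self._locus_plans):
            chrom = self.chroms[i % len(self.chroms)]
            cls = plan["class"]
            if plan["violation"] == "near_gene":
                gene = self._cursor.place(chrom, int(rng.integers(800, 2000)), gap=700)
                self.tair_features.append((self._stranded(gene), "protein_coding"))
                self._genes_placed += 1
                gap = int(rng.integers(80, 350))  # < 500 bp from that gene
            else:
                gap = 700  # >= 500 bp from whatever precedes
            if cls == "short":
                span = self._cursor.place(chrom, int(rng.integers(120, 196)), gap=gap)
                exon_ivs = [span]
            else:
                exon_ivs, span = self._place_exons(chrom, cls, gap)
            plan.update(chrom=chrom, span=span, exons=exon_ivs)
            if plan["violation"] == "te" or (
                cls == "orf_coding" and rng.random() < 0.3
            ):
                e0 = exon_ivs[0]
                te_len = int(rng.integers(150, 400))
                te = GenomicInterval(
                    chrom, max(0, e0.start - te_len // 2), e0.start + te_len // 2 + 1
                )
                self.te_features.append((te, "TE"))
                plan["te_overlap"] = True
            else:
                plan["te_overlap"] = False
            if plan["novelty"] == "recent":
                pad = int(rng.integers(0, 120))
                feat = GenomicInterval(
                    chrom, max(0, span.start - pad), span.end + pad
                )
                self.araport_extra.append((feat, "other_gene"))

    def _place_exons(self, chrom: str, cls: str, gap: int):
        rng = self.rng
        if cls == "orf_coding":
            n_exons = 1  # keeps the planted ORF contiguous in the genome
            exon_lens = [int(rng.integers(600, 1500))]
        else:
            n_exons = int(rng.integers(1, 4))
            exon_lens = [int(rng.integers(200, 700)) for _ in range(n_exons)]
        ivs = []
        for j, ln in enumerate(exon_lens):
            ivs.append(self._cursor.place(chrom, ln, gap=gap if j == 0 else 0))
            if j < n_exons - 1:
                # intron: advance the cursor without emitting a feature
                self._cursor.pos[chrom] += int(rng.integers(60, 300))
        span = GenomicInterval(chrom, ivs[0].start, ivs[-1].end)
        return ivs, span

    # ------------------------------------------------------------ transcripts

    def generate_novel_transcripts(self) -> None:
        cfg = self.config
        rng = self.rng
        tcons_counter = 1
        for plan in self._locus_plans:
            strand = plan["strand"]
            exons = [
                GenomicInterval(e.chrom, e.start, e.end, strand if strand != "." else ".")
                for e in plan["exons"]
            ]
            primary = TranscriptModel(
                tcons_id=f"TCONS_{tcons_counter:08d}", exons=exons, strand=strand
            )
            tcons_counter += 1
            models = [primary]
            if plan["multi"]:
                iso_exons = self._isoform_exons(exons, strand)
                models.append(
                    TranscriptModel(
                        tcons_id=f"TCONS_{tcons_counter:08d}",
                        exons=iso_exons,
                        strand=strand,
                    )
                )
                tcons_counter += 1
            plan["models"] = models
            plan["primary"] = primary
            if plan["class"] == "orf_coding":
                plan["orf"] = self._write_orf(primary)
            else:
                plan["orf"] = None
        # decoy transcripts overlapping the older annotation (to be excluded)
        decoy_genes = [
            iv for iv, b in self.tair_features if b == "protein_coding"
        ][: cfg.n_known_decoys]
        if len(decoy_genes) < cfg.n_known_decoys:
            raise SizingError("not enough reference genes to host known decoys")
        self._decoys = []
        for iv in decoy_genes:
            exon = GenomicInterval(
                iv.chrom, iv.start + 10, min(iv.end, iv.start + 10 + 400), "."
            )
            self._decoys.append(
                TranscriptModel(tcons_id=f"TCONS_{tcons_counter:08d}", exons=[exon], strand=".")
            )
            tcons_counter += 1

        self._plant_mirna_sites()
        self._sanitize_noncoding()

        # locus ids via the same grouping rule the pipeline uses
        all_models = [m for p in self._locus_plans for m in p["models"]] + self._decoys
        group_into_loci(all_models)
        self.transcripts = all_models
        self._build_truth_skeleton()

    def _isoform_exons(self, exons, strand):
        """A shorter overlapping isoform: truncated copy of the first exon(s)."""
        rng = self.rng
        e0 = exons[0]
        ln = min(len(e0), max(150, int(len(e0) * rng.uniform(0.4, 0.8))))
        first = GenomicInterval(e0.chrom, e0.start, e0.start + ln, e0.strand)
        return [first] + [dataclasses.replace(e) for e in exons[1:-1]]

    def _splice_map(self, t: TranscriptModel) -> np.ndarray:
        """Plus-orientation spliced position -> genomic position."""
        return np.concatenate([np.arange(e.start, e.end) for e in t.exons])

    def _plus_spliced_seq(self, t: TranscriptModel) -> str:
        arr = self.genome_arrays[t.chrom]
        return b"".join(arr[e.start:e.end].tobytes() for e in t.exons).decode()

    def _write_spliced(self, t: TranscriptModel, pos: int, text: str) -> None:
        gmap = self._splice_map(t)
        arr = self.genome_arrays[t.chrom]
        for k, ch in enumerate(text):
            arr[gmap[pos + k]] = ch.encode()

    def _write_orf(self, t: TranscriptModel) -> dict:
        """Plant an ATG..stop ORF of >= 100 codons in the (plus-strand)
        primary transcript; returns its spliced offset and frame."""
        rng = self.rng
        n = t.spliced_length
        max_aa = (n - 20) // 3 - 2
        aa = int(rng.integers(100, min(380, max_aa) + 1))
        offset = int(rng.integers(3, n - 3 * (aa + 2) - 3))
        codons = [ _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), aa) ]
        orf_seq = "ATG" + "".join(codons) + "TAA"
        self._write_spliced(t, offset, orf_seq)
        return {"offset": offset, "aa": aa, "frame": offset % 3,
                "span": (offset, offset + len(orf_seq))}

    def _plant_mirna_sites(self) -> None:
        cfg = self.config
        rng = self.rng
        for i in range(cfg.n_mirnas):
            seq = "".join(rng.choice(list("ACGT"), size=cfg.mirna_length))
            self.mirnas[f"miR-sim-{i + 1:02d}"] = seq
        eligible = [
            p for p in self._locus_plans
            if p["strand"] in ("+", ".") and p["primary"].spliced_length >= cfg.mirna_length + 40
        ]
        n_targets = int(round(cfg.mirna_target_fraction * cfg.n_novel_loci))
        idx = rng.choice(len(eligible), size=min(n_targets, len(eligible)), replace=False)
        mirna_ids = sorted(self.mirnas)
        for j in sorted(idx):
            plan = eligible[j]
            t = plan["primary"]
            mid = mirna_ids[int(rng.integers(0, len(mirna_ids)))]
            mseq = self.mirnas[mid]
            site = _revcomp(mseq)
            mode = "cleavage"
            expectation = 0.0
            if rng.random() < 0.2:
                # mismatch at miRNA position 10: central, seed-doubled -> 2.0
                m = len(mseq)
                k = m - 10  # site index facing miRNA position 10
                orig = site[k]
                alt = {"A": "C", "C": "A", "G": "A", "T": "C"}[orig]
                # avoid turning the mismatch into a G:U wobble
                if (mseq[9], alt) in (("G", "T"), ("T", "G")):
                    alt = "C" if alt != "C" else "A"
                site = site[:k] + alt + site[k + 1:]
                mode = "translational_inhibition"
                expectation = 2.0
            lo = 10
            hi = t.spliced_length - len(site) - 10
            if plan["orf"] is not None:
                s0, s1 = plan["orf"]["span"]
                pos = s1 + 3
                if pos + len(site) > t.spliced_length - 3:
                    if s0 - 3 - len(site) >= 3:
                        pos = 3  # upstream of the planted ORF instead
                    else:
                        continue  # no room without touching the ORF
            else:
                pos = int(rng.integers(lo, max(lo + 1, hi)))
            self._write_spliced(t, pos, site)
            plan.setdefault("mirna_sites", []).append(
                {"mirna": mid, "position": pos, "mode": mode, "expectation": expectation}
            )
            gmap = self._splice_map(t)
            plan.setdefault("protected_genomic", set()).update(
                int(g) for g in gmap[pos: pos + len(site)]
            )

    def _sanitize_noncoding(self, orf_min_aa: int = 100, max_rounds: int = 60) -> None:
        """Remove accidental >= 100-codon ORFs from noncoding loci by
        injecting stop codons (outside planted miRNA sites)."""
        for plan in self._locus_plans:
            if plan["class"] == "orf_coding":
                continue
            for t in plan["models"]:
                protected = plan.get("protected_genomic", set())
                gmap = self._splice_map(t)
                for _ in range(max_rounds):
                    seq = self._plus_spliced_seq(t)
                    long_orfs = [
                        o for o in find_orfs(seq, "both")
                        if o.peptide_length >= orf_min_aa
                    ]
                    if not long_orfs:
                        break
                    o = long_orfs[0]
                    n = len(seq)
                    placed = False
                    for frac in (0.5, 0.3, 0.7, 0.2, 0.8, 0.4, 0.6):
                        ci = o.start + 3 * (3 + int(frac * (o.peptide_length - 6)))
                        if o.strand == "+":
                            p, text = ci, "TAA"
                        else:
                            p, text = n - ci - 3, _revcomp("TAA")
                        if not any(int(gmap[p + k]) in protected for k in range(3)):
                            self._write_spliced(t, p, text)
                            placed = True
                            break
                    if not placed:  # pragma: no cover - degenerate geometry
                        raise SizingError(
                            f"{t.tcons_id}: cannot sanitize ORF without touching "
                            "a planted miRNA site"
                        )
                else:  # pragma: no cover
                    raise SizingError(f"{t.tcons_id}: ORF sanitation did not converge")

    def _build_truth_skeleton(self) -> None:
        for plan in self._locus_plans:
            primary = plan["primary"]
            xloc = primary.xloc_id
            plan["xloc"] = xloc
            self.truth[xloc] = LocusTruth(
                xloc_id=xloc,
                tcons=[m.tcons_id for m in plan["models"]],
                primary_tcons=primary.tcons_id,
                biotype=plan["class"],
                novelty=plan["novelty"],
                strand=plan["strand"],
                te_overlap=plan["te_overlap"],
                linc_distance_ok=plan["class"] == "lincRNA"
                or (plan["class"] != "lncRNA" or plan["violation"] != "near_gene"),
                mean_rpm={}, lfc={}, dex={}, pex={}, hpex={}, present={}, psx=False,
                stratum="", homology_bin="none",
                considered_rpf=False, translated=False,
                orf_frame=None if plan["orf"] is None else plan["orf"]["frame"],
                mirna_sites=plan.get("mirna_sites", []),
            )
        for d in getattr(self, "_decoys", []):
            self.truth[d.xloc_id] = LocusTruth(
                xloc_id=d.xloc_id, tcons=[d.tcons_id], primary_tcons=d.tcons_id,
                biotype="lncRNA", novelty="known", strand=".", te_overlap=False,
                linc_distance_ok=False, mean_rpm={}, lfc={}, dex={}, pex={},
                hpex={}, present={}, psx=False, stratum="", homology_bin="none",
                considered_rpf=False, translated=False, orf_frame=None,
                mirna_sites=[],
            )

    # ------------------------------------------------------------ counts

    # planted mean-RPM grid; every value (and its x4 / /4 image under the
    # default fold change) stays well clear of the 1 and 10 RPM thresholds
    _BASE_LOW, _BASE_MID, _BASE_HIGH = 4.0, 30.0, 100.0

    def generate_counts(self) -> None:
        cfg = self.config
        rng = self.rng
        if cfg.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        xlocs = [p["xloc"] for p in self._locus_plans] + [
            d.xloc_id for d in getattr(self, "_decoys", [])
        ]
        n = len(xlocs)
        fold = 2.0 ** abs(cfg.planted_lfc)

        psx_flags = rng.random(len(self._locus_plans)) < cfg.psx_fraction
        gp_flags = rng.random(len(self._locus_plans)) < cfg.germinated_expressed_fraction

        sample_rows = []
        col_means: dict[str, np.ndarray] = {}
        conditions = ("control", "HS")
        for ds in cfg.datasets:
            pollen = ds in cfg.pollen_datasets
            germ = pollen and cfg.pollen_datasets.index(ds) >= 2
            means = {c: np.zeros(n) for c in conditions}
            for i, plan in enumerate(self._locus_plans):
                truth = self.truth[plan["xloc"]]
                if pollen:
                    expressed = True if not germ else bool(gp_flags[i])
                else:
                    expressed = not bool(psx_flags[i])
                if not expressed:
                    ctl = hs = 0.0
                    lfc = 0.0
                elif pollen and rng.random() < cfg.de_fraction:
                    base = self._BASE_MID if rng.random() < 0.6 else self._BASE_HIGH
                    if rng.random() < 0.5:
                        ctl, hs, lfc = base, base * fold, abs(cfg.planted_lfc)
                    else:
                        ctl, hs, lfc = base * fold, base, -abs(cfg.planted_lfc)
                else:
                    u = rng.random()
                    if not pollen:
                        base = 8.0 if u < 0.5 else self._BASE_MID
                    elif u > cfg.hpex_fraction:
                        base = self._BASE_LOW
                    else:
                        base = self._BASE_MID if u < 0.55 else self._BASE_HIGH
                    ctl = hs = base
                    lfc = 0.0
                means["control"][i] = ctl
                means["HS"][i] = hs
                truth.mean_rpm[ds] = {"control": ctl, "HS": hs}
                truth.lfc[ds] = lfc
                truth.dex[ds] = abs(lfc) >= 1.0 and max(ctl, hs) > 0
                truth.present[ds] = max(ctl, hs) >= 0.05
                if pollen:
                    truth.pex[ds] = max(ctl, hs) > 1.0
                    truth.hpex[ds] = max(ctl, hs) > 10.0
            for cond in conditions:
                for rep in range(1, cfg.replicates_per_condition + 1):
                    lib = int(round(cfg.library_size * rng.uniform(0.9, 1.1)))
                    name = f"{ds}_{cond}_{rep}"
                    mu = means[cond] * lib / 1e6
                    counts = np.zeros(n, dtype=np.int64)
                    pos = mu > 0
                    lam = rng.gamma(
                        1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu[pos]
                    )
                    counts[pos] = rng.poisson(lam)
                    col_means[name] = counts
                    sample_rows.append(
                        {
                            "dataset": ds, "sample": name, "condition": cond,
                            "replicate": rep, "library_size": lib,
                            "tissue": "pollen" if pollen else "sporophyte",
                        }
                    )
        for plan in self._locus_plans:
            truth = self.truth[plan["xloc"]]
            sporo_quiet = all(
                max(truth.mean_rpm[ds].values()) < 1.0
                for ds in cfg.sporophytic_datasets
            )
            truth.psx = any(truth.pex.values()) and sporo_quiet
        for d in getattr(self, "_decoys", []):
            truth = self.truth[d.xloc_id]
            for ds in cfg.datasets:
                truth.mean_rpm[ds] = {"control": 0.0, "HS": 0.0}
                truth.lfc[ds] = 0.0
                truth.dex[ds] = False
                truth.present[ds] = False
                if ds in cfg.pollen_datasets:
                    truth.pex[ds] = truth.hpex[ds] = False
        self.counts = pd.DataFrame(col_means, index=xlocs)
        self.samples = pd.DataFrame(sample_rows)

    # ------------------------------------------------------------ P-sites

    def generate_psite_tracks(self) -> None:
        """Tracks for the germinating-pollen (third) dataset's RPF libraries.

        Translated loci draw in-frame counts at ``psite_signal_rate`` and
        off-frame at ``psite_noise_rate``; translated truth additionally
        enforces >= 5 PF positions in the ORF frame and < 5 in the others,
        and considered-but-untranslated loci < 5 in every frame, so the
        planted flags are exactly recoverable.
        """
        from .ribo import PsiteTrack

        cfg = self.config
        rng = self.rng
        if len(cfg.pollen_datasets) < 3:
            return
        gp = cfg.pollen_datasets[2]
        lib = cfg.rpf_library_size
        min_rpm_counts = int(np.ceil(lib / 1e6))  # counts for 1 RPM
        self.tracks = {"control": {}, "HS": {}}
        for plan in self._locus_plans:
            truth = self.truth[plan["xloc"]]
            t = plan["primary"]
            n = t.spliced_length
            gp_expressed = max(truth.mean_rpm[gp].values()) > 0
            if not gp_expressed:
                continue
            self.track_lengths[t.tcons_id] = n
            is_coding = plan["class"] == "orf_coding"
            translated = is_coding and rng.random() < cfg.translated_fraction
            considered = translated or rng.random() < 0.5
            frame = plan["orf"]["frame"] if translated else None
            per_cond: dict[str, np.ndarray] = {}
            for cond in ("control", "HS"):
                counts = np.zeros(n, dtype=np.int64)
                if considered:
                    counts = rng.poisson(cfg.psite_noise_rate, size=n)
                    if translated:
                        o = plan["orf"]
                        inpos = np.arange(o["span"][0], o["span"][1] - 3, 3)
                        counts[inpos] = rng.poisson(cfg.psite_signal_rate, len(inpos))
                        if (counts[inpos] > 0).sum() < 5:
                            counts[inpos[:5]] = np.maximum(counts[inpos[:5]], 1)
                else:
                    if rng.random() < 0.5:
                        counts[int(rng.integers(0, n))] = 1  # sub-RPM stray signal
                per_cond[cond] = counts
            if considered:
                # enforce the planted call on the condition-pooled track:
                # < 5 PF positions in every frame except the planted ORF frame
                pooled_occ = (per_cond["control"] > 0) | (per_cond["HS"] > 0)
                for f in range(3):
                    if f == frame:
                        continue
                    occupied = np.flatnonzero(pooled_occ & (np.arange(n) % 3 == f))
                    if len(occupied) >= 5:
                        for counts in per_cond.values():
                            counts[occupied[4:]] = 0
                for counts in per_cond.values():
                    total = counts.sum()
                    if total < min_rpm_counts * 2:
                        boost = np.flatnonzero(counts > 0)
                        if len(boost) == 0:
                            counts[0 if frame is None else frame] = 1
                            boost = np.flatnonzero(counts > 0)
                        counts[boost[0]] += min_rpm_counts * 2 - total
            for cond, counts in per_cond.items():
                self.tracks[cond][t.tcons_id] = PsiteTrack(t.tcons_id, counts, lib)
            truth.considered_rpf = considered
            truth.translated = translated

    # ------------------------------------------------------------ homology

    def generate_homology_tables(self) -> None:
        cfg = self.config
        rng = self.rng
        strata = list(cfg.stratum_mix)
        probs = np.array([cfg.stratum_mix[s] for s in strata])
        rows = []
        brows = []
        for plan in self._locus_plans:
            truth = self.truth[plan["xloc"]]
            query = plan["xloc"]
            stratum = strata[int(rng.choice(len(strata), p=probs))]
            truth.stratum = stratum
            if stratum != FOCAL_LINEAGE.species:
                taxon = NODE_TO_TAXON[stratum]
                for _ in range(int(rng.integers(1, 4))):
                    rows.append(
                        (query, taxon, round(rng.uniform(75, 99), 1),
                         10.0 ** rng.uniform(-30, -6))
                    )
                # extra hits from younger nodes never move the stratum rootward
                younger = [
                    NODE_TO_TAXON[n]
                    for n in _NODE_ORDER[1:_NODE_ORDER.index(stratum)]
                ]
                for taxon2 in younger:
                    if rng.random() < 0.5:
                        rows.append(
                            (query, taxon2, round(rng.uniform(80, 99), 1),
                             10.0 ** rng.uniform(-30, -6))
                        )
            if rng.random() < 0.2:
                # decoy failing the E-value filter, from an older node
                older_i = min(_NODE_ORDER.index(stratum) + 1, len(_NODE_ORDER) - 1)
                if _NODE_ORDER[older_i] != stratum:
                    rows.append(
                        (query, NODE_TO_TAXON[_NODE_ORDER[older_i]],
                         round(rng.uniform(70, 90), 1), 10.0 ** rng.uniform(-4, -1))
                    )
            # protein (blastx-style) homology bins
            if rng.random() < cfg.homology_fraction:
                full = rng.random() < 0.3
                ident = rng.uniform(97, 100) if full else rng.uniform(50, 96.4)
                brows.append(
                    (query, f"prot_{query}", round(ident, 1), 10.0 ** rng.uniform(-40, -8))
                )
                truth.homology_bin = "full" if full else "partial"
            elif rng.random() < 0.15:
                brows.append(
                    (query, f"prot_{query}", round(rng.uniform(50, 99), 1),
                     10.0 ** rng.uniform(-6.5, -3))
                )  # fails the 1e-7 filter -> bin stays none
        self.phylo_hits = pd.DataFrame(
            rows, columns=["query", "subject_taxon", "pident", "evalue"]
        )
        self.blastx_hits = pd.DataFrame(
            brows, columns=["qseqid", "sseqid", "pident", "evalue"]
        )

    # ------------------------------------------------------------ output

    @property
    def genome(self) -> dict[str, str]:
        return {c: a.tobytes().decode() for c, a in self.genome_arrays.items()}

    def annotation_sets(self) -> tuple[AnnotationSet, AnnotationSet, AnnotationSet]:
        tair = AnnotationSet(list(self.tair_features))
        araport = AnnotationSet(list(self.tair_features) + list(self.araport_extra))
        te = AnnotationSet(list(self.te_features))
        return tair, araport, te

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(config=self.config, loci=self.truth)

    def write(self, outdir: str | Path) -> None:
        from . import ribo

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        gtfio.write_fasta(self.genome, out / "genome.fa")
        tair, araport, te = self.annotation_sets()
        gtfio.write_annotation_gff3(tair, out / "reference_tair.gff3")
        gtfio.write_annotation_gff3(araport, out / "reference_araport.gff3")
        gtfio.write_annotation_gff3(te, out / "te.gff3")
        gtfio.write_transcript_gtf(self.transcripts, out / "transcripts.gtf")
        self.counts.rename_axis("locus").to_csv(out / "counts.tsv", sep="\t")
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        ribo.write_tracks(self.tracks, self.track_lengths, out / "psite_tracks.tsv")
        self.phylo_hits.to_csv(out / "phylo_hits.tsv", sep="\t", header=False, index=False)
        with open(out / "lineages.tsv", "w") as fh:
            fh.write(f"{FOCAL_LINEAGE.species}\t{';'.join(FOCAL_LINEAGE.nodes)}\n")
            for taxon, lin in sorted(TAXA_LINEAGES.items()):
                fh.write(f"{taxon}\t{';'.join(lin.nodes)}\n")
        self.blastx_hits.to_csv(out / "blastx_hits.tsv", sep="\t", header=False, index=False)
        gtfio.write_fasta(self.mirnas, out / "mirnas.fa")
        self.ground_truth().to_json(out / "ground_truth.json")


def simulate_run(config: SimConfig, outdir: str | Path | None = None) -> Simulation:
    """Run every generator stage in the documented order; optionally write files."""
    sim = Simulation(config)
    sim.generate_genome_and_annotation()
    sim.generate_novel_transcripts()
    sim.generate_counts()
    sim.generate_psite_tracks()
    sim.generate_homology_tables()
    if outdir is not None:
        sim.write(outdir)
    return sim
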