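"""Readers and writers for the standard formats the pipeline speaks.

VCF v4.2 (per-strain DP/AD genotypes; read through pysam), BED and
bedGraph, GFF3 (read through gffutils), FASTA (Biopython), and the
tabular SV / recombination-map / liftover formats. Coordinates are
0-based half-open internally, 1-based in VCF, half-open in BED.
"""

from __future__ import annotations

import math
import tempfile

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import GeneModel, VariantSite
from .sv import SvEvent

__all__ = [
    "write_strain_vcf", "read_strain_vcf", "write_founder_vcf",
    "read_founder_vcf", "write_bed", "read_bed", "write_bedgraph",
    "write_gff3", "read_gff3", "write_fasta", "read_fasta",
    "write_sv_tsv", "read_sv_tsv", "write_recomb_map", "read_recomb_map",
    "write_haploblocks_bed", "write_liftover", "read_liftover",
]


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contigs: dict, samples, extra_info=()):
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=REPDIST,Number=1,Type=Integer,'
                 'Description="Distance in bp to nearest repeat element">')
    lines.append('##INFO=<ID=CATALOG,Number=0,Type=Flag,'
                 'Description="Present in the known-variant catalog">')
    for line in extra_info:
        lines.append(line)
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref, alt)">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return lines


def _gt(site: VariantSite, strain: str) -> str:
    frac = site.alt_fraction(strain)
    if site.depth.get(strain, 0) == 0:
        return "./."
    if frac >= 0.9:
        return "1/1"
    if frac >= 0.1:
        return "0/1"
    return "0/0"


def write_strain_vcf(path, sites, strains, contigs: dict,
                     classes: dict | None = None) -> None:
    """Write per-site DP/AD for both strains; optional per-site class in
    INFO (``CLASS=``) for classified call sets."""
    lines = _vcf_header(
        contigs, strains,
        extra_info=('##INFO=<ID=CLASS,Number=1,Type=String,'
                    'Description="Variant class">',) if classes is not None else ())
    for i, s in enumerate(sites):
        info = []
        if math.isfinite(s.repeat_distance):
            info.append(f"REPDIST={int(s.repeat_distance)}")
        if s.in_catalog:
            info.append("CATALOG")
        if classes is not None and i in classes:
            info.append(f"CLASS={classes[i]}")
        fields = [s.chrom, str(s.pos), ".", s.ref, s.alt, ".", "PASS",
                  ";".join(info) or ".", "GT:DP:AD"]
        for st in strains:
            d = s.depth.get(st, 0)
            a = s.alt_support.get(st, 0)
            fields.append(f"{_gt(s, st)}:{d}:{d - a},{a}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_strain_vcf(path):
    """Read a two-strain VCF into ``VariantSite`` records.

    Multi-allelic records are decomposed into biallelic ones (the
    classification rules are stated per variant allele). Returns
    ``(sites, strain_names, classes)`` where ``classes`` maps site index
    to the INFO ``CLASS`` value when present.
    """
    sites, classes = [], {}
    with pysam.VariantFile(path) as vf:
        strains = list(vf.header.samples)
        for rec in vf:
            for ai, alt in enumerate(rec.alts or ()):
                depth, support = {}, {}
                for st in strains:
                    smp = rec.samples[st]
                    depth[st] = int(smp.get("DP") or 0)
                    ad = smp.get("AD")
                    support[st] = int(ad[ai + 1]) if ad and ad[ai + 1] is not None \
                        else 0
                site = VariantSite(
                    rec.chrom, rec.pos, rec.ref, alt, depth, support,
                    repeat_distance=float(rec.info.get("REPDIST", math.inf)),
                    in_catalog=bool(rec.info.get("CATALOG", False)))
                if "CLASS" in rec.info:
                    classes[len(sites)] = rec.info["CLASS"]
                sites.append(site)
    return sites, strains, classes


def write_founder_vcf(path, panel, contigs: dict) -> None:
    """Founder panel as a multi-sample VCF (homozygous GT calls)."""
    lines = _vcf_header(contigs, panel.founder_names)
    for i in range(panel.n_sites):
        gts = ["1/1" if panel.alleles[f, i] else "0/0"
               for f in range(panel.n_founders)]
        fields = [panel.chrom, str(int(panel.positions[i]) + 1), ".",
                  str(panel.ref[i]), str(panel.alt[i]), ".", "PASS", ".",
                  "GT"] + gts
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_founder_vcf(path):
    """Read a founder panel VCF back into a ``FounderPanel`` (without the
    latent unknown haplotype, which is truth-side only)."""
    from .simulate import FounderPanel

    positions, refs, alts, rows = [], [], [], []
    with pysam.VariantFile(path) as vf:
        founders = tuple(vf.header.samples)
        chrom = None
        for rec in vf:
            chrom = rec.chrom
            positions.append(rec.pos - 1)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            rows.append([1 if any(a == 1 for a in (rec.samples[f]["GT"] or ()))
                         else 0 for f in founders])
    return FounderPanel(
        chrom, np.array(positions), np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array(rows, dtype=np.int8).T, founders, None)


# ---------------------------------------------------------------------------
# BED / bedGraph


def write_bed(path, intervals, chrom: str = "chr1", names=None) -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "name", "score", "strand",
                  "thickStart", "thickEnd", "itemRgb"][: df.shape[1]]
    return df


def write_bedgraph(path, track: pd.DataFrame, value_col: str = "density") -> None:
    track[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False)


def write_haploblocks_bed(path, haploblocks) -> None:
    """BED9: ancestry label in name, mean posterior scaled to score."""
    with open(path, "w") as fh:
        for b in haploblocks:
            score = int(round(1000 * b.mean_posterior)) \
                if math.isfinite(b.mean_posterior) else 0
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.label_str}\t{score}\t."
                     f"\t{b.start}\t{b.end}\t0,0,0\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(path, genes) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n")
            for j, (s, e) in enumerate(sorted(g.cds)):
                fh.write(f"{g.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={g.gene_id}.cds{j};Parent={g.gene_id}\n")


def read_gff3(path):
    """Parse gene models (gene + CDS features) from a GFF3 file."""
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(str(path), tmp.name, force=True,
                                merge_strategy="create_unique")
        genes = []
        for g in db.features_of_type("gene"):
            cds = [(c.start - 1, c.end)
                   for c in db.children(g, featuretype="CDS")]
            genes.append(GeneModel(
                g.id, g.seqid, g.strand, sorted(cds),
                g.attributes.get("biotype", ["protein_coding"])[0]))
    return genes


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path, seqs: dict) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# tabular


def write_sv_tsv(path, events, strain_names) -> None:
    a, b = strain_names
    rows = [{
        "chrom": ev.chrom, "start": ev.start, "end": ev.end, "type": ev.svtype,
        "source_strain": ev.source_strain or "",
        f"support_{a}": ev.support.get(a, 0),
        f"support_{b}": ev.support.get(b, 0),
        "chrom2": ev.chrom2 or "", "pos2": "" if ev.pos2 is None else ev.pos2,
    } for ev in events]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path, strain_names):
    a, b = strain_names
    df = pd.read_csv(path, sep="\t", dtype={"chrom2": str})
    events = []
    for r in df.itertuples(index=False):
        pos2 = getattr(r, "pos2", "")
        chrom2 = getattr(r, "chrom2", "")
        events.append(SvEvent(
            r.chrom, int(r.start), int(r.end), r.type,
            support={a: int(getattr(r, f"support_{a}")),
                     b: int(getattr(r, f"support_{b}"))},
            source_strain=r.source_strain or None,
            chrom2=None if pd.isna(chrom2) or chrom2 == "" else str(chrom2),
            pos2=None if pd.isna(pos2) or pos2 == "" else int(pos2)))
    return events


def write_recomb_map(path, recomb_map) -> None:
    pd.DataFrame(recomb_map, columns=["position", "rate_cM_Mb"]).to_csv(
        path, sep="\t", index=False)


def read_recomb_map(path):
    df = pd.read_csv(path, sep="\t")
    return [(int(p), float(r)) for p, r in
            zip(df["position"], df["rate_cM_Mb"])]


def write_liftover(path, table) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_liftover(path):
    from .genome import LiftoverTable

    return LiftoverTable.from_frame(pd.read_csv(path, sep="\t"))
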