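"""Readers and writers: phased VCF, PLINK genetic maps, haplotype CSVs and
the gzipped-JSON tree exchange format.

All coordinates are 1-based and inclusive (VCF convention).  Multiallelic
records are rejected rather than auto-split: splitting silently changes
branch order downstream, so the user is asked to pre-split with standard
tools (e.g. ``bcftools norm -m-``).
"""

from __future__ import annotations

import gzip
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import GeneticMap, Haplotype, HaplotypeMatrix, VariantInfo
from .hst import Hst, HstNode

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "read_haplotype_csv",
    "write_haplotype_csv",
    "read_hst",
    "write_hst",
]

_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")

HST_FORMAT_VERSION = "1.0"


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected contig:start-end")
    contig, start, end = m.group(1), m.group(2), m.group(3)
    return contig, (int(start) if start else None), (int(end) if end else None)


def read_phased_vcf(path: str | Path, region: str | None = None) -> HaplotypeMatrix:
    """Read a phased, biallelic VCF/VCF.gz into a haplotype matrix.

    One row per sample haplotype in sample order (sample1-hap1,
    sample1-hap2, sample2-hap1, ...).  Any unphased, missing, haploid or
    multiallelic record is an error: the tree algorithms require fully
    phased diploid biallelic data.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    contig = start = end = None
    if region is not None:
        contig, start, end = _parse_region(region)

    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if contig is not None and v.CHROM != contig:
            continue
        if start is not None and not (start <= v.POS <= end):
            continue
        if len(v.ALT) != 1:
            raise ValueError(
                f"{v.CHROM}:{v.POS}: multiallelic record; split before use "
                "(multiallelic sites should either be removed or split into "
                "individual rows)"
            )
        gts = v.genotypes
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for si, gt in enumerate(gts):
            if len(gt) != 3:
                raise ValueError(
                    f"{v.CHROM}:{v.POS} sample {samples[si]}: non-diploid genotype"
                )
            a1, a2, phased = gt
            if a1 < 0 or a2 < 0:
                raise ValueError(
                    f"{v.CHROM}:{v.POS} sample {samples[si]}: missing allele"
                )
            if not phased:
                raise ValueError(
                    f"{v.CHROM}:{v.POS} sample {samples[si]}: unphased genotype"
                )
            col[2 * si] = a1
            col[2 * si + 1] = a2
        variants.append(
            VariantInfo(v.CHROM, v.POS, v.ID or ".", v.REF, v.ALT[0])
        )
        columns.append(col)
    vcf.close()
    if not variants:
        raise ValueError(f"{path}: no biallelic records" + (f" in {region}" if region else ""))
    data = np.stack(columns, axis=1)
    return HaplotypeMatrix(variants=variants, data=data, sample_ids=samples, ploidy=2)


def write_phased_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a matrix back to a minimal GT-only phased VCF (.vcf or .vcf.gz)."""
    if matrix.ploidy != 2:
        raise ValueError("VCF output requires diploid rows (ploidy 2)")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, var in enumerate(matrix.variants):
            col = matrix.data[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(matrix.n_samples)
            )
            fh.write(
                f"{var.contig}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Parse a 4-column PLINK-format genetic map (chrom, id, cM, bp)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cM", "bp"],
        dtype={"chrom": str},
        comment="#",
    )
    if len(df) < 2:
        raise ValueError(f"{path}: genetic map needs at least 2 rows")
    contigs = df["chrom"].unique()
    if len(contigs) > 1:
        raise ValueError(
            f"{path}: one contig per map file, found {sorted(contigs)}"
        )
    df = df.sort_values("bp", kind="stable")
    bp = df["bp"].to_numpy(dtype=np.int64)
    cm = df["cM"].to_numpy(dtype=np.float64)
    if np.any(np.diff(bp) <= 0):
        raise ValueError(f"{path}: duplicate bp positions in genetic map")
    if np.any(np.diff(cm) < 0):
        raise ValueError(f"{path}: non-monotone genetic map (cM decreases with bp)")
    return GeneticMap(contig=str(contigs[0]), bp=bp, cM=cm)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for bp, cm in zip(gmap.bp, gmap.cM):
            fh.write(f"{gmap.contig}\t.\t{cm:.8g}\t{bp}\n")


def read_haplotype_csv(path: str | Path) -> Haplotype:
    """Read a haplotype CSV (header contig,pos,id,ref,alt,allele)."""
    df = pd.read_csv(path, dtype={"contig": str})
    required = {"contig", "pos", "id", "ref", "alt", "allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing haplotype CSV columns {sorted(missing)}")
    df = df.sort_values("pos", kind="stable")
    variants = [
        VariantInfo(str(r.contig), int(r.pos), str(r.id), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    return Haplotype(variants=variants, alleles=df["allele"].to_numpy(dtype=np.uint8))


def write_haplotype_csv(hap: Haplotype, path: str | Path) -> None:
    rows = [
        {"contig": v.contig, "pos": v.pos, "id": v.id, "ref": v.ref,
         "alt": v.alt, "allele": int(a)}
        for v, a in zip(hap.variants, hap.alleles)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HST exchange format: gzipped JSON (.hst.gz); plain JSON accepted on read.
# Unknown extra fields are preserved so third-party deposits survive a
# read/write cycle.
# ---------------------------------------------------------------------------

def write_hst(hst: Hst, path: str | Path) -> None:
    doc = {
        "format_version": HST_FORMAT_VERSION,
        "coords": {"contig": hst.contig, "start_pos": hst.start_pos},
        "direction": hst.direction,
        "variants": [
            {"contig": v.contig, "pos": v.pos, "id": v.id, "ref": v.ref, "alt": v.alt}
            for v in hst.variants
        ],
        "samples": None if hst.anonymized else list(hst.samples or []),
        "min_node_size": hst.min_node_size,
        "start_marker_idx": hst.start_marker_idx,
        "nodes": {
            str(n.id): {
                **({} if hst.anonymized else {"indexes": [int(i) for i in n.indexes]}),
                "n": int(n.n),
                "start_idx": n.start_idx,
                "stop_idx": n.stop_idx,
                "haplotype": [[int(m), int(a)] for m, a in n.haplotype],
                **n.extra,
            }
            for n in hst.nodes.values()
        },
        "edges": [
            [int(parent.id), int(child_id)]
            for parent in hst.nodes.values()
            for child_id in parent.children
        ],
        **hst.extra,
    }
    payload = json.dumps(doc, separators=(",", ":")).encode()
    path = Path(path)
    with open(path, "wb") as raw:
        # mtime pinned so identical trees yield identical bytes
        with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
            gz.write(payload)


_NODE_KEYS = {"indexes", "n", "start_idx", "stop_idx", "haplotype"}
_TOP_KEYS = {
    "format_version", "coords", "direction", "variants", "samples",
    "min_node_size", "start_marker_idx", "nodes", "edges",
}


def read_hst(path: str | Path) -> Hst:
    """Read a tree file; gzip is sniffed, plain JSON accepted."""
    raw = Path(path).read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    doc = json.loads(raw.decode())
    for key in ("coords", "direction", "variants", "nodes", "edges"):
        if key not in doc:
            raise ValueError(f"{path}: HST file missing required key {key!r}")
    variants = [
        VariantInfo(str(v["contig"]), int(v["pos"]), str(v.get("id", ".")),
                    str(v["ref"]), str(v["alt"]))
        for v in doc["variants"]
    ]
    nodes: dict[int, HstNode] = {}
    for nid_s, nd in doc["nodes"].items():
        nid = int(nid_s)
        for key in ("n", "haplotype"):
            if key not in nd:
                raise ValueError(f"{path}: node {nid} missing required key {key!r}")
        indexes = nd.get("indexes")
        nodes[nid] = HstNode(
            id=nid,
            indexes=None if indexes is None else np.asarray(indexes, dtype=np.int64),
            n=int(nd["n"]),
            haplotype=[(int(m), int(a)) for m, a in nd["haplotype"]],
            start_idx=nd.get("start_idx"),
            stop_idx=nd.get("stop_idx"),
            children=[],
            extra={k: v for k, v in nd.items() if k not in _NODE_KEYS},
        )
    for parent_id, child_id in doc["edges"]:
        if parent_id not in nodes:
            raise ValueError(f"{path}: edge from nonexistent node {parent_id}")
        if child_id not in nodes:
            raise ValueError(
                f"{path}: node {parent_id} has edge to nonexistent node {child_id}"
            )
        nodes[parent_id].children.append(int(child_id))
    child_ids = {c for n in nodes.values() for c in n.children}
    roots = [nid for nid in nodes if nid not in child_ids]
    if len(roots) != 1:
        raise ValueError(f"{path}: tree must have exactly one root, found {roots}")
    samples = doc.get("samples")
    hst = Hst(
        direction=str(doc["direction"]),
        start_marker_idx=int(doc.get("start_marker_idx", 0)),
        variants=variants,
        nodes=nodes,
        root_id=roots[0],
        samples=None if samples is None else [str(s) for s in samples],
        min_node_size=int(doc.get("min_node_size", 1)),
        anonymized=samples is None,
        extra={k: v for k, v in doc.items() if k not in _TOP_KEYS},
    )
    hst.validate()
    return hst
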