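"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open; genes travel as a 6-column TSV
(gene_id, chrom, start, end, strand, biotype) or as GTF gene lines
(1-based closed coordinates, converted on read).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval

GENES_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split("\t")[:2]
        sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{s}\n" for c, s in sizes.items()))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file; extra columns are ignored."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    lines = []
    for i, iv in enumerate(intervals):
        cols = [iv.chrom, str(iv.start), str(iv.end)]
        if names is not None:
            cols.append(names[i])
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gene columns {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            strand=str(r.strand),
            biotype=str(r.biotype),
        )
        for r in df.itertuples()
    ]


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.strand,
            "biotype": g.biotype,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENES_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader: 'gene' feature lines only.

    GTF is 1-based closed; converted to 0-based half-open on read.
    """
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "gene":
            continue
        attrs = {}
        for item in f[8].strip().strip(";").split(";"):
            item = item.strip()
            if not item:
                continue
            key, _, val = item.partition(" ")
            attrs[key] = val.strip().strip('"')
        genes.append(
            GeneModel(
                gene_id=attrs.get("gene_id", f"{f[0]}:{f[3]}"),
                interval=GenomicInterval(f[0], int(f[3]) - 1, int(f[4])),
                strand=f[6],
                biotype=attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding")),
            )
        )
    return genes


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Feature x sample count table; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_bedgraph(
    chrom: str,
    starts: Sequence[int],
    ends: Sequence[int],
    values: Sequence[float],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
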