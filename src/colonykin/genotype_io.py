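"""Reading and writing genotype datasets and aligned sequences.

Two genotype representations are supported:

* a **CSV sample table** — the lossless native format.  One row per
  individual with metadata columns (``id, colony, caste, form, lat, long``,
  optional ``satellite_of``) followed by two allele columns per locus
  (``LOCUS.1, LOCUS.2``).  Haploid males leave the second allele cell empty;
  a fully empty pair means the locus is missing.

* **GENEPOP** text files for interoperability with the classical analysis
  tools.  GENEPOP is diploid-only, so haploid males are encoded as
  homozygotes and the truth about ploidy, caste, form and coordinates is
  carried in a sidecar CSV written next to the ``.gen`` file
  (``<path>.meta.csv``).  Reading merges the sidecar back in when present.

Aligned mtDNA goes through plain FASTA via Biopython.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (ColonyMeta, DatasetError, GenotypeDataset, Individual,
                        MarkerPanel, SequenceAlignment)


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


META_COLUMNS = ["id", "colony", "caste", "form", "lat", "long", "satellite_of"]


# ---------------------------------------------------------------------------
# CSV sample table
# ---------------------------------------------------------------------------

def read_sample_table(path) -> GenotypeDataset:
    """Read the native CSV sample table.

    Loci are inferred from paired ``NAME.1``/``NAME.2`` columns; the marker
    panel is inferred from the observed alleles.  Males must be haploid: a
    male row with two distinct alleles at a locus is a ploidy error.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "colony", "caste", "form"}
    if not required.issubset(df.columns):
        raise ParseError(f"sample table must have columns {sorted(required)}")
    loci = []
    for col in df.columns:
        if col.endswith(".1"):
            name = col[:-2]
            if f"{name}.2" in df.columns:
                loci.append(name)
    if not loci:
        raise ParseError("no locus columns (NAME.1/NAME.2 pairs) found")

    individuals = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        rec = dict(zip(df.columns, row))
        caste = rec["caste"].strip().lower()
        form = rec["form"].strip().lower()
        geno = {}
        for locus in loci:
            a1 = rec[f"{locus}.1"].strip()
            a2 = rec[f"{locus}.2"].strip()
            if a1 == "" and a2 == "":
                geno[locus] = None
                continue
            if caste == "male":
                if a2 != "" and a2 != a1:
                    raise ParseError(
                        f"line {row_no}: male {rec['id']} has two distinct alleles at {locus}")
                geno[locus] = (int(a1),)
            else:
                if a1 == "" or a2 == "":
                    geno[locus] = None
                else:
                    geno[locus] = (int(a1), int(a2))
        try:
            individuals.append(Individual(rec["id"], rec["colony"], caste, form, geno))
        except DatasetError as exc:
            raise ParseError(f"line {row_no}: {exc}") from exc

    colonies = _colony_metas_from_table(df)
    panel = MarkerPanel.from_genotypes(loci, individuals)
    return GenotypeDataset(panel, individuals, colonies)


def _colony_metas_from_table(df: pd.DataFrame) -> list:
    metas = {}
    for _, row in df.iterrows():
        cid = row["colony"]
        if cid in metas:
            continue
        lat = row.get("lat", "")
        lon = row.get("long", "")
        sat = row.get("satellite_of", "") if "satellite_of" in df.columns else ""
        metas[cid] = ColonyMeta(
            cid, row["form"].strip().lower(),
            float(lat) if lat not in ("", None) else None,
            float(lon) if lon not in ("", None) else None,
            sat if sat not in ("", None) else None)
    return list(metas.values())


def write_sample_table(dataset: GenotypeDataset, path) -> None:
    """Write the lossless CSV sample table (deterministic row/column order)."""
    loci = dataset.panel.locus_names
    cmap = dataset.colony_map
    rows = []
    for ind in sorted(dataset.individuals, key=lambda i: (i.colony, i.id)):
        meta = cmap[ind.colony]
        row = {"id": ind.id, "colony": ind.colony, "caste": ind.caste, "form": ind.form,
               "lat": "" if meta.latitude is None else repr(meta.latitude),
               "long": "" if meta.longitude is None else repr(meta.longitude),
               "satellite_of": meta.satellite_of or ""}
        for locus in loci:
            g = ind.genotype.get(locus)
            row[f"{locus}.1"] = "" if g is None else str(g[0])
            row[f"{locus}.2"] = "" if g is None or len(g) == 1 else str(g[1])
        rows.append(row)
    cols = META_COLUMNS + [f"{l}.{k}" for l in loci for k in (1, 2)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.csv")


def write_genepop(dataset: GenotypeDataset, path, partition_by: str = "colony",
                  allele_digits: int = 3) -> None:
    """Write a GENEPOP file plus the ploidy/metadata sidecar.

    ``partition_by`` selects the POP blocks: ``colony``,
    ``caste-within-colony`` or ``form``.  Output ordering is deterministic
    (partitions then individuals, lexicographic), so identical datasets
    produce byte-identical files.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    if partition_by not in ("colony", "caste-within-colony", "form"):
        raise ValueError(f"unknown partition_by {partition_by!r}")
    limit = 10 ** allele_digits
    loci = dataset.panel.locus_names

    def key(ind):
        if partition_by == "colony":
            return (ind.colony,)
        if partition_by == "form":
            return (ind.form,)
        return (ind.colony, ind.caste)

    groups: dict[tuple, list] = {}
    for ind in dataset.individuals:
        groups.setdefault(key(ind), []).append(ind)
    if not groups:
        raise ValueError("refusing to write GENEPOP file with no individuals (empty POP block)")

    lines = [f"colonykin export; partition_by={partition_by}; allele_digits={allele_digits}"]
    lines.extend(loci)
    for gkey in sorted(groups):
        lines.append("POP")
        for ind in sorted(groups[gkey], key=lambda i: i.id):
            fields = []
            for locus in loci:
                g = ind.genotype.get(locus)
                if g is None:
                    fields.append("0" * (2 * allele_digits))
                    continue
                a, b = (g[0], g[0]) if len(g) == 1 else g
                if a >= limit or b >= limit:
                    raise ValueError(f"allele {max(a, b)} at {locus} does not fit {allele_digits} digits")
                fields.append(f"{a:0{allele_digits}d}{b:0{allele_digits}d}")
            lines.append(f"{ind.id}, " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")

    cmap = dataset.colony_map
    with open(_sidecar_path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(META_COLUMNS)
        for ind in sorted(dataset.individuals, key=lambda i: (i.colony, i.id)):
            meta = cmap[ind.colony]
            w.writerow([ind.id, ind.colony, ind.caste, ind.form,
                        "" if meta.latitude is None else repr(meta.latitude),
                        "" if meta.longitude is None else repr(meta.longitude),
                        meta.satellite_of or ""])


def read_genepop(path, allele_digits: int = 3, sidecar=None) -> GenotypeDataset:
    """Read a GENEPOP file (title line, locus lines, POP-delimited samples).

    An all-zero allele field decodes as missing.  If a metadata sidecar
    (``<path>.meta.csv`` or an explicit ``sidecar`` path) is present, ploidy,
    caste, form, colony names and coordinates are merged from it; otherwise
    every sample is treated as a diploid worker and POP blocks become
    colonies named ``POP1``, ``POP2``, ...
    """
    if allele_digits not in (2, 3):
        raise ParseError("allele width must be 2 or 3 digits")
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("file too short to be GENEPOP")

    meta = _read_sidecar(sidecar if sidecar is not None else _sidecar_path(path))

    # locus declarations: everything between the title and the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in lines[i].replace(",", "\n").splitlines():
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise ParseError("no POP line found")
    if len(set(loci)) != len(loci):
        raise ParseError("duplicate locus names in header")

    width = 2 * allele_digits
    individuals = []
    pop_index = 0
    seen_ids = set()
    for line_no in range(i, len(lines)):
        raw = lines[line_no].strip()
        if not raw:
            continue
        if raw.upper() == "POP":
            pop_index += 1
            continue
        if "," not in raw:
            raise ParseError(f"line {line_no + 1}: expected 'id, genotypes'")
        sample_id, _, geno_part = raw.partition(",")
        sample_id = sample_id.strip()
        if sample_id in seen_ids:
            raise ParseError(f"line {line_no + 1}: duplicate sample id {sample_id!r}")
        seen_ids.add(sample_id)
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"line {line_no + 1}: {len(fields)} genotype fields for {len(loci)} loci")
        info = meta.get(sample_id, {})
        caste = info.get("caste", "worker")
        geno = {}
        for locus, fld in zip(loci, fields):
            if len(fld) != width:
                raise ParseError(
                    f"line {line_no + 1}: field {fld!r} at {locus} is not {width} chars wide")
            a, b = int(fld[:allele_digits]), int(fld[allele_digits:])
            if a == 0 or b == 0:
                geno[locus] = None
            elif caste == "male":
                geno[locus] = (a,)  # homozygous encoding of a haploid
            else:
                geno[locus] = (a, b)
        colony = info.get("colony", f"POP{pop_index}")
        form = info.get("form", "annual")
        individuals.append(Individual(sample_id, colony, caste, form, geno))

    colonies = _colony_metas_from_sidecar(meta, individuals)
    panel = MarkerPanel.from_genotypes(loci, individuals)
    return GenotypeDataset(panel, individuals, colonies)


def _read_sidecar(path) -> dict:
    p = Path(path)
    if not p.exists():
        return {}
    out = {}
    with open(p, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["id"]] = row
    return out


def _colony_metas_from_sidecar(meta: dict, individuals) -> list:
    metas: dict[str, ColonyMeta] = {}
    for ind in individuals:
        if ind.colony in metas:
            continue
        info = meta.get(ind.id, {})
        lat = info.get("lat", "")
        lon = info.get("long", "")
        sat = info.get("satellite_of", "")
        metas[ind.colony] = ColonyMeta(
            ind.colony, ind.form,
            float(lat) if lat else None, float(lon) if lon else None, sat or None)
    return list(metas.values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> SequenceAlignment:
    """Read an aligned FASTA file; sequences are uppercased, gaps preserved."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        ref = len(records[0][1])
        bad = [rid for rid, s in records if len(s) != ref]
        raise DatasetError(f"alignment has ragged lengths; offending ids: {bad}")
    return SequenceAlignment(tuple(records))


def write_fasta(alignment: SequenceAlignment, path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment.records]
    SeqIO.write(recs, str(path), "fasta")
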