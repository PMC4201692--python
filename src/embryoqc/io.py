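"""Text-format readers and writers.

Supported formats:

* PLINK ``.ped``/``.map`` (whitespace-separated).  The ``.map`` may carry the
  standard 4 columns (chrom, locus_id, cM, bp) or an extended 6-column variant
  with the two design alleles appended; the writer always emits 6 columns so
  that round-trips are exact.  Alleles "0 0" encode NO_CALL; chromosome "30"
  is accepted as an alias for X and emitted as "X".
* GenomeStudio-style "final report" TSV with a ``[Data]`` section and columns
  ``SNP Name, Sample ID, Allele1, Allele2, GC Score`` (AB allele coding,
  "-" = missing).
* Pedigree as a 4-column TSV (individual, sire, dam, sex).
* Marker-effect table as TSV (locus_id, one column per trait) with index
  weights/scale/offset carried in ``#``-prefixed header lines.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    FEMALE,
    HET,
    HOM_A,
    HOM_B,
    MALE,
    NO_CALL,
    SEX_UNKNOWN,
    UNKNOWN_PARENT,
    GenotypeMatrix,
    Pedigree,
    PedigreeRecord,
    make_locus_table,
    normalize_chrom,
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

_SEX_TO_PLINK = {MALE: "1", FEMALE: "2", SEX_UNKNOWN: "0"}
_PLINK_TO_SEX = {"1": MALE, "2": FEMALE}


def read_plink(ped_path, map_path) -> tuple[GenotypeMatrix, Pedigree]:
    """Read a PED/MAP pair into a genotype matrix plus pedigree."""
    loci_raw = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) not in (4, 6):
                raise ParseError(
                    f"{map_path}:{lineno}: expected 4 or 6 columns, got {len(fields)}"
                )
            loci_raw.append(fields)
    n_loci = len(loci_raw)

    samples, records = [], []
    call_rows = []
    allele_seen: list[dict] = [dict() for _ in range(n_loci)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_loci:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} fields "
                    f"for {n_loci} loci, got {len(fields)}"
                )
            _fid, iid, sire, dam, sexcode, _pheno = fields[:6]
            samples.append(iid)
            records.append(
                PedigreeRecord(iid, sire, dam, _PLINK_TO_SEX.get(sexcode, SEX_UNKNOWN))
            )
            alleles = fields[6:]
            for j in range(n_loci):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                for a in (a1, a2):
                    if a != "0" and len(a) != 1:
                        raise ParseError(
                            f"{ped_path}:{lineno}: bad allele {a!r} at locus {j + 1}"
                        )
                    if a != "0":
                        allele_seen[j].setdefault(a, len(allele_seen[j]))
            call_rows.append(alleles)

    # resolve design alleles
    allele_a, allele_b = [], []
    for j, fields in enumerate(loci_raw):
        if len(fields) == 6:
            allele_a.append(fields[4])
            allele_b.append(fields[5])
        else:
            seen = sorted(allele_seen[j], key=allele_seen[j].get)
            a = seen[0] if seen else "A"
            b = seen[1] if len(seen) > 1 else ("B" if a != "B" else "A2")
            allele_a.append(a)
            allele_b.append(b)

    calls = np.full((len(samples), n_loci), NO_CALL, dtype=np.int8)
    for i, alleles in enumerate(call_rows):
        for j in range(n_loci):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            dose = 0
            for a in (a1, a2):
                if a == allele_b[j]:
                    dose += 1
                elif a != allele_a[j]:
                    raise ParseError(
                        f"{ped_path}: sample {samples[i]!r} locus "
                        f"{loci_raw[j][1]!r}: allele {a!r} not in "
                        f"({allele_a[j]!r}, {allele_b[j]!r})"
                    )
            calls[i, j] = dose

    loci = make_locus_table(
        [f[1] for f in loci_raw],
        [normalize_chrom(f[0]) for f in loci_raw],
        [int(float(f[3])) for f in loci_raw],
        allele_a,
        allele_b,
        genetic_pos_cM=[float(f[2]) for f in loci_raw],
    )
    matrix = GenotypeMatrix(samples, loci, calls)
    # parents referenced but not genotyped in this file become stub records
    present = {r.individual_id for r in records}
    for r in list(records):
        for pid, sex in ((r.sire_id, MALE), (r.dam_id, FEMALE)):
            if pid != UNKNOWN_PARENT and pid not in present:
                records.append(PedigreeRecord(pid, sex=sex))
                present.add(pid)
    return matrix, Pedigree(records)


def write_plink(matrix: GenotypeMatrix, pedigree: Pedigree | None, out_prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and a 6-column ``<prefix>.map``."""
    ped_path = Path(str(out_prefix) + ".ped")
    map_path = Path(str(out_prefix) + ".map")

    loci = matrix.loci
    cm = (
        loci["genetic_pos_cM"]
        if "genetic_pos_cM" in loci.columns
        else pd.Series(np.zeros(len(loci)))
    )
    with open(map_path, "w") as fh:
        for i in range(len(loci)):
            row = loci.iloc[i]
            fh.write(
                f"{row['chromosome']}\t{row['locus_id']}\t{cm.iloc[i]:g}\t"
                f"{row['position_bp']}\t{row['allele_a']}\t{row['allele_b']}\n"
            )

    a = loci["allele_a"].to_numpy()
    b = loci["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(matrix.sample_ids):
            if pedigree is not None and iid in pedigree:
                rec = pedigree.get(iid)
            else:
                rec = PedigreeRecord(iid)
            head = [
                iid,
                iid,
                rec.sire_id,
                rec.dam_id,
                _SEX_TO_PLINK[rec.sex],
                "-9",
            ]
            parts = []
            row = matrix.calls[i]
            for j in range(matrix.n_loci):
                c = row[j]
                if c == NO_CALL:
                    parts.append("0 0")
                elif c == HOM_A:
                    parts.append(f"{a[j]} {a[j]}")
                elif c == HET:
                    parts.append(f"{a[j]} {b[j]}")
                else:
                    parts.append(f"{b[j]} {b[j]}")
            fh.write(" ".join(head) + " " + " ".join(parts) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# GenomeStudio-style final report
# ---------------------------------------------------------------------------

_FR_COLUMNS = ["SNP Name", "Sample ID", "Allele1", "Allele2", "GC Score"]


def read_final_report(path, loci: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a final-report TSV (AB allele coding, per-call GC score).

    Loci are ordered by the supplied map if given, else by first appearance.
    """
    with open(path) as fh:
        lines = fh.readlines()
    # skip optional header block
    start = 0
    for i, line in enumerate(lines):
        if line.strip() == "[Data]":
            start = i + 1
            break
    header = None
    for i in range(start, len(lines)):
        if lines[i].strip():
            header = [c.strip() for c in lines[i].rstrip("\n").split("\t")]
            start = i + 1
            break
    if header is None:
        raise ParseError(f"{path}: no data rows found")
    colmap = {}
    for want in _FR_COLUMNS:
        for k, col in enumerate(header):
            if col == want or col.startswith(want + " "):
                colmap[want] = k
                break
        else:
            raise ParseError(
                f"{path}: required column {want!r} not found; columns present: {header}"
            )

    entries: dict[tuple[str, str], tuple[int, float]] = {}
    sample_order: list[str] = []
    locus_order: list[str] = []
    seen_samples, seen_loci = set(), set()
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        snp = fields[colmap["SNP Name"]].strip()
        sid = fields[colmap["Sample ID"]].strip()
        a1 = fields[colmap["Allele1"]].strip()
        a2 = fields[colmap["Allele2"]].strip()
        gc_raw = fields[colmap["GC Score"]].strip()
        if sid not in seen_samples:
            seen_samples.add(sid)
            sample_order.append(sid)
        if snp not in seen_loci:
            seen_loci.add(snp)
            locus_order.append(snp)
        if a1 in ("-", "0") or a2 in ("-", "0"):
            call = NO_CALL
        else:
            try:
                call = sum(1 for x in (a1, a2) if x == "B")
                if any(x not in ("A", "B") for x in (a1, a2)):
                    raise ValueError
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: alleles must be A/B/-, got {a1!r} {a2!r}"
                ) from None
        try:
            gc = float(gc_raw) if gc_raw not in ("", "NA", "NaN") else np.nan
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad GC Score {gc_raw!r}") from None
        entries[(sid, snp)] = (call, gc)

    if loci is None:
        loci = make_locus_table(
            locus_order, ["1"] * len(locus_order), np.arange(1, len(locus_order) + 1)
        )
    locus_ids = list(loci["locus_id"])
    calls = np.full((len(sample_order), len(locus_ids)), NO_CALL, dtype=np.int8)
    quality = np.full(calls.shape, np.nan)
    for (sid, snp), (call, gc) in entries.items():
        try:
            j = locus_ids.index(snp)
        except ValueError:
            continue
        i = sample_order.index(sid)
        calls[i, j] = call
        quality[i, j] = gc
    return GenotypeMatrix(sample_order, loci, calls, quality)


def write_final_report(matrix: GenotypeMatrix, path) -> Path:
    """Write a final-report TSV mirroring the GenomeStudio dialect."""
    path = Path(path)
    code_to_ab = {HOM_A: ("A", "A"), HET: ("A", "B"), HOM_B: ("B", "B"), NO_CALL: ("-", "-")}
    with open(path, "w") as fh:
        fh.write("[Header]\n")
        fh.write(f"Num Samples\t{matrix.n_samples}\n")
        fh.write(f"Num SNPs\t{matrix.n_loci}\n")
        fh.write("[Data]\n")
        fh.write("SNP Name\tSample ID\tAllele1 - AB\tAllele2 - AB\tGC Score\n")
        for i, sid in enumerate(matrix.sample_ids):
            for j, snp in enumerate(matrix.loci["locus_id"]):
                a1, a2 = code_to_ab[int(matrix.calls[i, j])]
                if matrix.quality is None or not np.isfinite(matrix.quality[i, j]):
                    gc = "NA"
                else:
                    gc = f"{matrix.quality[i, j]:.4f}"
                fh.write(f"{snp}\t{sid}\t{a1}\t{a2}\t{gc}\n")
    return path


# ---------------------------------------------------------------------------
# Pedigree TSV
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    """Read a 4-column TSV: individual_id, sire_id, dam_id, sex (M/F/U)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if lineno == 1 and fields[0].lower() in ("individual_id", "id"):
                continue
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            iid, sire, dam, sex = fields
            sex = {"1": MALE, "2": FEMALE}.get(sex, sex)
            if sex not in (MALE, FEMALE, SEX_UNKNOWN):
                sex = SEX_UNKNOWN
            records.append(PedigreeRecord(iid, sire, dam, sex))
    return Pedigree(records)


def write_pedigree(pedigree: Pedigree, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual_id\tsire_id\tdam_id\tsex\n")
        for r in pedigree:
            fh.write(f"{r.individual_id}\t{r.sire_id}\t{r.dam_id}\t{r.sex}\n")
    return path


# ---------------------------------------------------------------------------
# Marker effects
# ---------------------------------------------------------------------------

@dataclass
class MarkerEffectSet:
    """Per-locus additive effects per trait plus selection-index weights.

    ``effects`` is indexed by locus_id with one column per trait; the effect
    is per copy of allele B.  The index combines standardized trait values
    with ``index_weights`` and maps them to points via ``index_scale`` and
    ``index_offset``.
    """

    effects: pd.DataFrame
    index_weights: pd.Series
    index_scale: float = 100.0
    index_offset: float = 0.0

    def __post_init__(self):
        self.effects = self.effects.astype(float)
        self.index_weights = pd.Series(self.index_weights, dtype=float)
        missing = set(self.effects.columns) - set(self.index_weights.index)
        if missing:
            raise ValueError(f"index_weights missing traits {sorted(missing)}")
        if not np.isfinite(self.effects.to_numpy()).all():
            raise ValueError("effects must be finite")
        if not np.isfinite(self.index_weights.to_numpy()).all():
            raise ValueError("index weights must be finite")
        if self.index_scale <= 0:
            raise ValueError("index_scale must be positive")

    @property
    def trait_names(self) -> list[str]:
        return list(self.effects.columns)


def read_marker_effects(path) -> MarkerEffectSet:
    weights = {}
    scale, offset = 100.0, 0.0
    header_lines = []
    with open(path) as fh:
        body = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            else:
                body.append(line)
    for line in header_lines:
        parts = line.split()
        if parts[0] == "index_weight":
            weights[parts[1]] = float(parts[2])
        elif parts[0] == "index_scale":
            scale = float(parts[1])
        elif parts[0] == "index_offset":
            offset = float(parts[1])
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", index_col="locus_id")
    if not weights:
        weights = {t: 1.0 for t in df.columns}
    return MarkerEffectSet(df, pd.Series(weights), scale, offset)


def write_marker_effects(effects: MarkerEffectSet, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for t, w in effects.index_weights.items():
            fh.write(f"#index_weight {t} {w:g}\n")
        fh.write(f"#index_scale {effects.index_scale:g}\n")
        fh.write(f"#index_offset {effects.index_offset:g}\n")
        effects.effects.to_csv(fh, sep="\t", index_label="locus_id")
    return path
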