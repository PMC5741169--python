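"""Read and write phased cohorts, sample panels, and archaic diplotypes.

The internal model mirrors phased VCF v4.1: a variant table, a {0,1}
allele matrix with two haplotype columns per sample, a sample panel
mapping each sample to its population and continent, and an ancestral
status per variant parsed from the INFO ``AA=`` field ("R" the reference
allele is ancestral, "M" the alternative allele is ancestral, "X"
unknown).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantRecord",
    "PhasedCohort",
    "ArchaicDiplotype",
    "parse_ancestral",
    "read_panel",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_archaic_vcf",
]

_BASES = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant.

    ``ancestral_status`` is "R" (reference allele ancestral), "M"
    (alternative allele ancestral) or "X" (unknown). ``alt_count`` is the
    number of alternative-allele copies among the 2n haplotypes.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    vid: str
    ref_allele: str
    alt_allele: str
    ancestral_status: str
    alt_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ancestral_status not in ("R", "M", "X"):
            raise ValueError(f"bad ancestral status {self.ancestral_status!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass
class PhasedCohort:
    """A phased diploid cohort over one or more chromosomes.

    ``alleles`` has shape (n_variants, 2n); columns 2i and 2i+1 are the two
    parental haplotypes of sample i.  ``panel`` maps each sample id to a
    (population, continent) pair.
    """

    records: list[VariantRecord]
    alleles: np.ndarray
    samples: list[str]
    panel: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.shape != (len(self.records), 2 * len(self.samples)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.records)} variants x {2 * len(self.samples)} haplotypes"
            )
        missing = [s for s in self.samples if s not in self.panel]
        if missing:
            raise ValueError(f"samples absent from panel: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.pos for r in self.records], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([r.chrom for r in self.records])

    @property
    def statuses(self) -> np.ndarray:
        """Per-variant ancestral status in {R, M, X}."""
        return np.array([r.ancestral_status for r in self.records])

    def continent_of_column(self, j: int) -> str:
        return self.panel[self.samples[j // 2]][1]

    @property
    def column_continents(self) -> np.ndarray:
        """Continent label for each of the 2n haplotype columns."""
        return np.array(
            [self.panel[s][1] for s in self.samples for _ in range(2)]
        )

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "id": [r.vid for r in self.records],
                "ref": [r.ref_allele for r in self.records],
                "alt": [r.alt_allele for r in self.records],
                "ancestral_status": [r.ancestral_status for r in self.records],
                "alt_count": [r.alt_count for r in self.records],
            }
        )


#: archaic diplotype codes: 0 hom-ref, 1 het, 2 hom-alt, x unresolved/absent
ARCHAIC_CODES = ("0", "1", "2", "x")


@dataclass
class ArchaicDiplotype:
    """Unphased archaic genotype codes aligned to a cohort's variant list."""

    codes: np.ndarray  # dtype '<U1', one of ARCHAIC_CODES

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        bad = set(self.codes.tolist()) - set(ARCHAIC_CODES)
        if bad:
            raise ValueError(f"invalid archaic codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.codes)


def parse_ancestral(aa_field: Optional[str], ref_allele: str, alt_allele: str) -> str:
    """Map an ``AA=`` INFO value to an ancestral status in {R, M, X}.

    Comparison is case-insensitive.  Anything that matches neither allele
    (absent field, ".", "-", "N", another base, indel mismatch) is unknown.
    """
    if aa_field is None:
        return "X"
    aa = str(aa_field).strip().upper()
    if aa == ref_allele.upper():
        return "R"
    if aa == alt_allele.upper():
        return "M"
    return "X"


def read_panel(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a 3-column (sample, population, continent) TSV; header optional."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"panel file {path} needs >= 3 columns")
    first = str(df.iloc[0, 0]).lower()
    if first in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    return {
        str(row.iloc[0]): (str(row.iloc[1]), str(row.iloc[2]))
        for _, row in df.iterrows()
    }


def _region_match(chrom: str, pos: int, region: Optional[tuple]) -> bool:
    if region is None:
        return True
    rchrom, start, end = region
    return chrom == rchrom and (start is None or start <= pos <= end)


def read_phased_vcf(
    path: str | Path,
    panel: str | Path | dict,
    region: Optional[tuple] = None,
    snp_only: bool = False,
) -> PhasedCohort:
    """Read a phased VCF v4.1 into a :class:`PhasedCohort`.

    Only biallelic records are retained (multi-allelic sites cannot be
    encoded in binary haplotype strings).  Any unphased ('/') or missing
    genotype in a retained record is a hard error naming the record, and
    every VCF sample must be present in the panel.

    ``region`` is an optional (chrom, start, end) tuple, 1-based inclusive;
    start/end may be None to take the whole chromosome.
    """
    panel_map = panel if isinstance(panel, dict) else read_panel(panel)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in panel_map]
    if absent:
        raise ValueError(
            f"samples present in VCF but absent from panel: {absent[:5]}"
        )

    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # multi-allelic records dropped
        ref, alt = v.REF, v.ALT[0]
        if snp_only and (len(ref) != 1 or len(alt) != 1):
            continue
        if not _region_match(v.CHROM, v.POS, region):
            continue
        where = f"{v.CHROM}:{v.POS}"
        gts = v.genotypes  # [allele_a, allele_b, phased] per sample
        row = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(gts):
            if len(gt) != 3:
                raise ValueError(
                    f"non-diploid genotype for sample {samples[i]} at {where}"
                )
            a, b, phased = gt
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[i]} at {where}"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype ('/') for sample {samples[i]} at {where}"
                )
            row[2 * i] = a
            row[2 * i + 1] = b
        aa = v.INFO.get("AA")
        status = parse_ancestral(aa, ref, alt)
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                vid=v.ID or ".",
                ref_allele=ref,
                alt_allele=alt,
                ancestral_status=status,
                alt_count=int(row.sum()),
            )
        )
        columns.append(row)

    order = sorted(
        range(len(records)), key=lambda i: (records[i].chrom, records[i].pos)
    )
    records = [records[i] for i in order]
    alleles = (
        np.array([columns[i] for i in order], dtype=np.uint8)
        if records
        else np.zeros((0, 2 * len(samples)), dtype=np.uint8)
    )
    return PhasedCohort(
        records=records,
        alleles=alleles,
        samples=samples,
        panel={s: panel_map[s] for s in samples},
    )


_STATUS_TO_AA = {"X": "."}


def write_phased_vcf(cohort: PhasedCohort, path: str | Path) -> None:
    """Write a cohort back to a phased VCF v4.1 with AA annotations."""
    chroms = sorted({r.chrom for r in cohort.records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for i, r in enumerate(cohort.records):
            if r.ancestral_status == "R":
                aa = r.ref_allele
            elif r.ancestral_status == "M":
                aa = r.alt_allele
            else:
                aa = "."
            row = cohort.alleles[i]
            gts = "\t".join(
                f"{row[2 * j]}|{row[2 * j + 1]}" for j in range(cohort.n_samples)
            )
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.vid}\t{r.ref_allele}\t{r.alt_allele}"
                f"\t.\tPASS\tAA={aa}\tGT\t{gts}\n"
            )


def write_panel(panel: dict[str, tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, (pop, continent) in panel.items():
            fh.write(f"{sample}\t{pop}\t{continent}\n")


def read_archaic_vcf(path: str | Path, cohort: PhasedCohort) -> ArchaicDiplotype:
    """Map an archaic (single-individual, unphased) VCF onto a cohort.

    Each cohort variant gets a code: 0 hom-ref, 1 het, 2 hom-alt; variants
    missing from the archaic file, uncallable, or with mismatching alleles
    get "x".  The archaic file is parsed as plain VCF text so malformed
    lines can be reported with their line number.
    """
    table: dict[tuple[str, int], tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValueError(
                    f"malformed archaic VCF line {lineno}: expected >= 10 "
                    f"tab-separated fields, got {len(parts)}"
                )
            chrom, pos_s, _vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(
                    f"malformed archaic VCF line {lineno}: bad POS {pos_s!r}"
                ) from exc
            gt = parts[9].split(":")[0]
            table[(chrom, pos)] = (ref, alt, gt)

    codes = np.full(len(cohort.records), "x", dtype="<U1")
    for i, r in enumerate(cohort.records):
        entry = table.get((r.chrom, r.pos))
        if entry is None:
            continue
        ref, alt, gt = entry
        if ref.upper() != r.ref_allele.upper():
            continue  # allele mismatch: unresolvable
        sep = "|" if "|" in gt else "/"
        fields = gt.split(sep)
        if len(fields) != 2 or any(f == "." for f in fields):
            continue
        try:
            a, b = (int(f) for f in fields)
        except ValueError:
            continue
        if {a, b} - {0, 1}:
            continue
        if (a or b) and alt.upper() != r.alt_allele.upper():
            continue  # carries a different alternative allele
        codes[i] = str(a + b)
    return ArchaicDiplotype(codes=codes)
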