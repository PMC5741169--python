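"""Constructive generator of phased cohorts with known haplotype truth.

Each segment is built top-down from an ancestral haplotype: a Yin
haplotype adds a chosen number of derived alleles, Yang is its
complement (optionally degraded to 47-49/50 by "jumped" positions where
Yang keeps the Yin allele), and a Mosaic haplotype places a subset of
Yin- and Yang-borne derived alleles on the ancestral background so that
its minimal piece count is exactly the configured value (self-checked at
generation time).  Haplotypes are dealt to samples with continent-specific
weights — ancestral and Mosaic haplotypes enriched in Africa, Yin avoiding
it — and remaining columns receive background haplotypes whose per-site
allele probabilities keep every planted variant frequent (MAF > 0.25).
An archaic individual is drawn near the ancestral haplotype (default 18%
derived alleles, <1% heterozygous).

Ground truth is exact by construction, so the whole pipeline is testable
without any external download.  Generation is purely constructive rather
than coalescent: linkage disequilibrium decay, recombination maps, and
demography are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONTINENTS
from .variant_io import (
    ArchaicDiplotype,
    PhasedCohort,
    VariantRecord,
    write_panel,
    write_phased_vcf,
)
from .haplotype_classes import min_pieces

__all__ = [
    "ScenarioSpec",
    "SynthConfig",
    "SegmentTruth",
    "SynthesisResult",
    "generate_cohort",
    "generate_toy_fixture",
    "TOY_VCF",
    "TOY_PANEL",
    "TOY_ARCHAIC_VCF",
]

#: Phase-1-like continental sample composition (1092 diploids).
DEFAULT_SAMPLES = {"AFR": 246, "AMR": 181, "ASN": 286, "EUR": 379}

_POP_OF = {"AFR": "YRI", "AMR": "MXL", "ASN": "CHB", "EUR": "CEU"}

SCENARIOS = ("yinyang", "yinyang+mosaic", "single-CH", "ancestral-rich", "no-CH")


@dataclass(frozen=True)
class ScenarioSpec:
    """Planted composition of one segment."""

    name: str
    yin_freq: float = 0.0
    yang_freq: float = 0.0
    mosaic_freq: float = 0.0
    single_ch_freq: float = 0.0
    n_ancestral: int = 0
    archaic_near_mosaic: bool = False

    @property
    def planted_freq(self) -> float:
        return (
            self.yin_freq + self.yang_freq + self.mosaic_freq + self.single_ch_freq
        )


_PRESETS: dict[str, ScenarioSpec] = {
    "yinyang": ScenarioSpec("yinyang", yin_freq=0.40, yang_freq=0.28),
    "yinyang+mosaic": ScenarioSpec(
        "yinyang+mosaic",
        yin_freq=0.40,
        yang_freq=0.28,
        mosaic_freq=0.08,
        archaic_near_mosaic=True,
    ),
    "single-CH": ScenarioSpec("single-CH", single_ch_freq=0.50),
    "ancestral-rich": ScenarioSpec(
        "ancestral-rich", yin_freq=0.40, yang_freq=0.28, n_ancestral=40
    ),
    "no-CH": ScenarioSpec("no-CH"),
}

#: continent weights for dealing each haplotype class
_CLASS_WEIGHTS = {
    "yin": {"AFR": 0.10, "AMR": 0.20, "ASN": 0.35, "EUR": 0.35},
    "yang": {"AFR": 0.15, "AMR": 0.20, "ASN": 0.32, "EUR": 0.33},
    "mosaic": {"AFR": 0.45, "AMR": 0.20, "ASN": 0.15, "EUR": 0.20},
    "single": {"AFR": 0.25, "AMR": 0.25, "ASN": 0.25, "EUR": 0.25},
    "ancestral": {"AFR": 0.75, "AMR": 0.10, "ASN": 0.05, "EUR": 0.10},
}


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the study cohort.

    ``scenarios`` lists the per-segment composition; ``d_yin`` is the
    number of derived alleles on Yin (Yang carries roughly the complement);
    ``n_jump`` Yang positions keep the Yin allele, degrading the pair to
    (50 - n_jump)/50 complementarity.  ``epsilon`` is a symmetric
    per-allele flip probability; ``x_fraction`` of variants get unknown
    (X) ancestral annotation.
    """

    samples_per_continent: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES)
    )
    scenarios: Sequence[str | ScenarioSpec] = SCENARIOS
    k: int = 50
    window_bp: int = 500_000
    chrom: str = "1"
    d_yin: int = 27
    n_jump: int = 2
    mosaic_pieces: int = 14
    mosaic_derived: int = 12
    mosaic_yin_match: int = 10
    epsilon: float = 0.0
    x_fraction: float = 0.10
    archaic_derived: float = 0.18
    archaic_het_rate: float = 0.005
    archaic_missing_rate: float = 0.02
    n_decoys: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 2 / self.k:
            raise ValueError("epsilon must be well below 2/k for recoverability")
        if self.n_jump > self.d_yin:
            raise ValueError("jumped positions live on Yin-derived sites")
        if self.mosaic_yin_match > self.mosaic_derived:
            raise ValueError("mosaic_yin_match cannot exceed mosaic_derived")
        for sc in self.scenario_specs():
            if sc.planted_freq > 0.9:
                raise ValueError(
                    f"scenario {sc.name}: planted frequencies must leave room "
                    "for background haplotypes"
                )

    def scenario_specs(self) -> list[ScenarioSpec]:
        out = []
        for s in self.scenarios:
            if isinstance(s, ScenarioSpec):
                out.append(s)
            elif s in _PRESETS:
                out.append(_PRESETS[s])
            else:
                raise ValueError(f"unknown scenario {s!r}")
        return out


@dataclass
class SegmentTruth:
    """Everything planted into one segment."""

    index: int
    scenario: str
    window_start: int
    positions: list[int]
    statuses: list[str]  # annotated statuses incl. X masking
    ancestral: str
    yin: Optional[str]
    yang: Optional[str]
    mosaic: Optional[str]
    single_ch: Optional[str]
    jumps: list[int]
    mosaic_pieces: Optional[int]
    mosaic_split: Optional[tuple[int, int, int]]
    class_counts: dict[str, int]
    class_continent_counts: dict[str, dict[str, int]]
    column_classes: np.ndarray  # per-haplotype-column class label
    archaic_hap: str  # '.', '0', '1' per position


@dataclass
class SynthesisResult:
    cohort: PhasedCohort
    archaic: ArchaicDiplotype
    truths: list[SegmentTruth]
    config: SynthConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCF + panel + archaic VCF + truth TSV into a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "panel": outdir / "panel.tsv",
            "archaic_vcf": outdir / "archaic.vcf",
            "truth": outdir / "truth_segments.tsv",
        }
        write_phased_vcf(self.cohort, paths["vcf"])
        write_panel(self.cohort.panel, paths["panel"])
        _write_archaic_vcf(self.cohort, self.archaic, paths["archaic_vcf"])
        truth_table(self.truths).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def truth_table(truths: Sequence[SegmentTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append(
            {
                "segment": t.index,
                "scenario": t.scenario,
                "window_start": t.window_start,
                "ancestral": t.ancestral,
                "yin": t.yin or "",
                "yang": t.yang or "",
                "mosaic": t.mosaic or "",
                "single_ch": t.single_ch or "",
                "mosaic_pieces": t.mosaic_pieces or 0,
                "n_yin": t.class_counts.get("yin", 0),
                "n_yang": t.class_counts.get("yang", 0),
                "n_mosaic": t.class_counts.get("mosaic", 0),
                "n_ancestral": t.class_counts.get("ancestral", 0),
            }
        )
    return pd.DataFrame(rows)


def _apportion(total: int, weights: dict[str, float], caps: dict[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` over continents."""
    conts = list(weights)
    raw = np.array([weights[c] for c in conts], dtype=float)
    raw = raw / raw.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    out = dict(zip(conts, base.tolist()))
    for c in conts:  # spill over if a continent is full
        over = out[c] - caps.get(c, 0)
        if over > 0:
            out[c] -= over
            for d in conts:
                room = caps.get(d, 0) - out[d]
                take = min(room, over)
                out[d] += take
                over -= take
                if not over:
                    break
    return out


def _compose_runs(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` positive integers."""
    if parts > total:
        raise ValueError("cannot split into more parts than items")
    cuts = np.sort(rng.choice(total - 1, parts - 1, replace=False)) + 1 if parts > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [total]])
    return np.diff(bounds)


def _build_mosaic_layout(
    n_pos: int,
    pieces: int,
    n_yin_match: int,
    n_yang_match: int,
    d_yin: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Choose Yin-derived sites and Mosaic flips realizing a piece count.

    Returns boolean arrays over the ``n_pos`` positions:
    (yin_derived, mosaic_flip_matching_yin, mosaic_flip_matching_yang).

    The per-position label of the Mosaic against a complementary Yin/Yang
    pair is Y wherever it matches Yin and G wherever it matches Yang; a
    sequence of ``pieces`` alternating label runs is laid out first and the
    derived-allele placement is solved from it.
    """
    n_y_runs = (pieces + 1) // 2
    n_g_runs = pieces // 2
    # label Y count follows from the derived-allele bookkeeping
    a = n_pos + n_yin_match - n_yang_match - d_yin
    if not (n_y_runs <= a and n_g_runs <= n_pos - a):
        raise ValueError(
            f"unconstructible mosaic: pieces={pieces} needs {n_y_runs} Y-runs "
            f"<= {a} Y-positions and {n_g_runs} G-runs <= {n_pos - a}"
        )
    if n_yin_match > a or n_yang_match > n_pos - a:
        raise ValueError("mosaic derived-allele split incompatible with layout")
    y_runs = _compose_runs(a, n_y_runs, rng)
    g_runs = _compose_runs(n_pos - a, n_g_runs, rng)
    labels = np.empty(n_pos, dtype="<U1")
    i = 0
    for j in range(pieces):
        run = y_runs[j // 2] if j % 2 == 0 else g_runs[j // 2]
        labels[i : i + run] = "Y" if j % 2 == 0 else "G"
        i += run
    y_pos = np.nonzero(labels == "Y")[0]
    g_pos = np.nonzero(labels == "G")[0]
    flips_y = rng.choice(y_pos, n_yin_match, replace=False)
    flips_g = rng.choice(g_pos, n_yang_match, replace=False)
    yin_derived = np.zeros(n_pos, dtype=bool)
    yin_derived[flips_y] = True
    g_mask = np.zeros(n_pos, dtype=bool)
    g_mask[g_pos] = True
    g_mask[flips_g] = False
    yin_derived |= g_mask
    fy = np.zeros(n_pos, dtype=bool)
    fy[flips_y] = True
    fg = np.zeros(n_pos, dtype=bool)
    fg[flips_g] = True
    return yin_derived, fy, fg


def _flip(anc: np.ndarray, where: np.ndarray) -> np.ndarray:
    out = anc.copy()
    out[where] = 1 - out[where]
    return out


def _as_str(bits: np.ndarray) -> str:
    return "".join(str(int(b)) for b in bits)


def generate_cohort(cfg: SynthConfig) -> SynthesisResult:
    """Generate a phased cohort, archaic diplotype, and exact truth tables."""
    rng = np.random.default_rng(cfg.seed)
    continents = [c for c in DEFAULT_CONTINENTS if c in cfg.samples_per_continent]
    samples: list[str] = []
    panel: dict[str, tuple[str, str]] = {}
    for cont in continents:
        for i in range(cfg.samples_per_continent[cont]):
            name = f"{cont}{i:04d}"
            samples.append(name)
            panel[name] = (_POP_OF.get(cont, cont), cont)
    n_hap = 2 * len(samples)
    col_cont = np.array([panel[s][1] for s in samples for _ in range(2)])
    cont_cols = {c: np.nonzero(col_cont == c)[0] for c in continents}

    specs = cfg.scenario_specs()
    k = cfg.k
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    truths: list[SegmentTruth] = []
    archaic_codes: list[str] = []

    for seg_i, sc in enumerate(specs):
        window_start = seg_i * cfg.window_bp
        positions = [window_start + 5001 + 1200 * j for j in range(k)]
        anc = rng.integers(0, 2, k).astype(np.uint8)  # ancestral allele per site

        jumps: list[int] = []
        yin = yang = mosaic = single = None
        mosaic_pieces_val: Optional[int] = None
        mosaic_split: Optional[tuple[int, int, int]] = None
        has_pair = sc.yin_freq > 0
        if has_pair:
            jump_count = min(cfg.n_jump, cfg.d_yin)
            if sc.mosaic_freq > 0:
                non_jump = k - jump_count
                yin_der_nj, fy, fg = _build_mosaic_layout(
                    non_jump,
                    cfg.mosaic_pieces,
                    cfg.mosaic_yin_match,
                    cfg.mosaic_derived - cfg.mosaic_yin_match,
                    cfg.d_yin - jump_count,
                    rng,
                )
                site_order = rng.permutation(k)
                jump_sites = np.sort(site_order[:jump_count])
                other_sites = np.sort(site_order[jump_count:])
                yin_derived = np.zeros(k, dtype=bool)
                yin_derived[other_sites] = yin_der_nj
                yin_derived[jump_sites] = True  # jumps sit on Yin-derived sites
                flips = np.zeros(k, dtype=bool)
                flips[other_sites] = fy | fg
                jumps = jump_sites.tolist()
                mosaic_bits = _flip(anc, flips)
            else:
                der_sites = rng.choice(k, cfg.d_yin, replace=False)
                yin_derived = np.zeros(k, dtype=bool)
                yin_derived[der_sites] = True
                jumps = sorted(
                    rng.choice(der_sites, jump_count, replace=False).tolist()
                )
                mosaic_bits = None
            yin_bits = _flip(anc, yin_derived)
            yang_bits = 1 - yin_bits
            yang_bits[jumps] = yin_bits[jumps]
            yin, yang = _as_str(yin_bits), _as_str(yang_bits)
            if mosaic_bits is not None:
                mosaic = _as_str(mosaic_bits)
                mosaic_pieces_val = min_pieces(mosaic, yin, yang)
                if mosaic_pieces_val != cfg.mosaic_pieces:
                    raise AssertionError(
                        f"mosaic self-check failed: built {mosaic_pieces_val} "
                        f"pieces, wanted {cfg.mosaic_pieces}"
                    )
                n_y = int(fy.sum())
                n_g = int(fg.sum())
                mosaic_split = (n_y, n_g, 0)
        if sc.single_ch_freq > 0:
            d = rng.choice(k, k // 2, replace=False)
            w = np.zeros(k, dtype=bool)
            w[d] = True
            single = _as_str(_flip(anc, w))

        anc_str = _as_str(anc)

        # deal haplotype classes to columns, continent-aware
        caps = {c: len(cont_cols[c]) for c in continents}
        free = {c: list(rng.permutation(cont_cols[c])) for c in continents}
        col_class = np.full(n_hap, "background", dtype="<U10")
        class_counts: dict[str, int] = {}
        class_cont: dict[str, dict[str, int]] = {}

        def deal(label: str, total: int, weights: dict[str, float]):
            if total <= 0:
                return
            per = _apportion(
                total,
                {c: weights.get(c, 0.0) for c in continents},
                {c: len(free[c]) for c in continents},
            )
            class_counts[label] = sum(per.values())
            class_cont[label] = dict(per)
            for c, m in per.items():
                for _ in range(m):
                    col_class[free[c].pop()] = label

        deal("yin", int(round(sc.yin_freq * n_hap)), _CLASS_WEIGHTS["yin"])
        deal("yang", int(round(sc.yang_freq * n_hap)), _CLASS_WEIGHTS["yang"])
        deal("mosaic", int(round(sc.mosaic_freq * n_hap)), _CLASS_WEIGHTS["mosaic"])
        deal("single", int(round(sc.single_ch_freq * n_hap)), _CLASS_WEIGHTS["single"])
        deal("ancestral", sc.n_ancestral, _CLASS_WEIGHTS["ancestral"])

        # background allele probabilities keep every site frequent
        planted = {
            "yin": yin,
            "yang": yang,
            "mosaic": mosaic,
            "single": single,
            "ancestral": anc_str,
        }
        q = np.zeros(k)
        f_bg = float(np.mean(col_class == "background"))
        for label, s in planted.items():
            if s is None or label not in class_counts:
                continue
            bits = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
            q += (class_counts[label] / n_hap) * bits
        # moderate probabilities keep backgrounds mutually diverse (no
        # spurious near-identity clusters) while every site stays frequent
        b = np.clip((0.5 - q) / max(f_bg, 1e-9), 0.15, 0.85)

        # X-masked annotation; keep Mosaic derived sites unmasked so the
        # derived-allele accounting of the truth tables stays exact
        n_x = int(round(cfg.x_fraction * k))
        maskable = np.arange(k)
        if mosaic is not None:
            mos_derived = np.array(
                [m != a for m, a in zip(mosaic, anc_str)], dtype=bool
            )
            maskable = maskable[~mos_derived]
        x_sites = set(
            rng.choice(maskable, min(n_x, len(maskable)), replace=False).tolist()
        )
        statuses = [
            "X" if j in x_sites else ("R" if anc[j] == 0 else "M")
            for j in range(k)
        ]
        unmasked = [j for j in range(k) if j not in x_sites]

        rep_bits = {
            label: np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
            for label, s in planted.items()
            if s is not None
        }

        def background_ok(vec: np.ndarray) -> bool:
            for label, bits in rep_bits.items():
                if label == "ancestral":
                    continue
                if int(np.sum(vec != bits)) <= 4:
                    return False
            aa = rep_bits["ancestral"]
            if sum(1 for j in unmasked if vec[j] != aa[j]) <= 4:
                return False
            return True

        seg_alleles = np.zeros((n_hap, k), dtype=np.uint8)
        anc_assigned = 0
        for col in range(n_hap):
            label = col_class[col]
            if label == "background":
                for _ in range(100):
                    vec = (rng.random(k) < b).astype(np.uint8)
                    if background_ok(vec):
                        break
                else:  # pragma: no cover - astronomically unlikely
                    raise RuntimeError("could not draw a background haplotype")
                seg_alleles[col] = vec
            elif label == "ancestral":
                vec = anc.copy()
                n_diff = anc_assigned % 3  # 0, 1 or 2 differences
                if n_diff:
                    where = rng.choice(unmasked, n_diff, replace=False)
                    vec[where] = 1 - vec[where]
                seg_alleles[col] = vec
                anc_assigned += 1
            else:
                seg_alleles[col] = rep_bits[label]

        if cfg.epsilon > 0:
            noise = rng.random(seg_alleles.shape) < cfg.epsilon
            seg_alleles = np.where(noise, 1 - seg_alleles, seg_alleles).astype(
                np.uint8
            )

        # archaic individual for this segment
        arch_hap = np.full(k, ".", dtype="<U1")
        arch_codes = np.full(k, "x", dtype="<U1")
        for j in range(k):
            if rng.random() < cfg.archaic_missing_rate:
                continue
            if sc.archaic_near_mosaic and mosaic is not None:
                allele = int(mosaic[j])
            else:
                derived = rng.random() < cfg.archaic_derived
                allele = int(1 - anc[j]) if derived else int(anc[j])
                if rng.random() < cfg.archaic_het_rate:
                    arch_codes[j] = "1"
                    continue
            arch_hap[j] = str(allele)
            arch_codes[j] = "0" if allele == 0 else "2"

        # emit variant records (planted sites + low-frequency decoys)
        for j in range(k):
            alt_count = int(seg_alleles[:, j].sum())
            records.append(
                VariantRecord(
                    chrom=cfg.chrom,
                    pos=positions[j],
                    vid=f"gv{len(records)}",
                    ref_allele="A",
                    alt_allele="G",
                    ancestral_status=statuses[j],
                    alt_count=alt_count,
                )
            )
            rows.append(seg_alleles[:, j].copy())
            archaic_codes.append(arch_codes[j])
        for d in range(cfg.n_decoys):
            pos = window_start + 5001 + 1200 * k + 500 * (d + 1)
            carriers = rng.choice(n_hap, max(1, n_hap // 50), replace=False)
            row = np.zeros(n_hap, dtype=np.uint8)
            row[carriers] = 1
            records.append(
                VariantRecord(
                    chrom=cfg.chrom,
                    pos=pos,
                    vid=f"gv{len(records)}",
                    ref_allele="C",
                    alt_allele="T",
                    ancestral_status="R",
                    alt_count=int(row.sum()),
                )
            )
            rows.append(row)
            archaic_codes.append("0")

        truths.append(
            SegmentTruth(
                index=seg_i,
                scenario=sc.name,
                window_start=window_start,
                positions=positions,
                statuses=statuses,
                ancestral=anc_str,
                yin=yin,
                yang=yang,
                mosaic=mosaic,
                single_ch=single,
                jumps=jumps,
                mosaic_pieces=mosaic_pieces_val,
                mosaic_split=mosaic_split,
                class_counts=class_counts,
                class_continent_counts=class_cont,
                column_classes=col_class,
                archaic_hap="".join(arch_hap),
            )
        )

    alleles = np.array(rows, dtype=np.uint8)
    cohort = PhasedCohort(
        records=records, alleles=alleles, samples=samples, panel=panel
    )
    archaic = ArchaicDiplotype(codes=np.array(archaic_codes, dtype="<U1"))
    return SynthesisResult(cohort=cohort, archaic=archaic, truths=truths, config=cfg)


def _write_archaic_vcf(
    cohort: PhasedCohort, archaic: ArchaicDiplotype, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tARCHAIC\n")
        gt_of = {"0": "0/0", "1": "0/1", "2": "1/1"}
        for rec, code in zip(cohort.records, archaic.codes):
            if code == "x":
                continue  # unresolved in the archaic genome
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.vid}\t{rec.ref_allele}\t"
                f"{rec.alt_allele}\t.\tPASS\t.\tGT\t{gt_of[code]}\n"
            )


# ---------------------------------------------------------------------------
# Tiny deterministic fixture: every value is hand-written and byte-stable.
# ---------------------------------------------------------------------------

TOY_VCF = """\
##fileformat=VCFv4.1
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t101\trs1\tA\tG\t.\tPASS\tAA=a\tGT\t0|1\t1|1\t0|0
1\t205\trs2\tC\tT\t.\tPASS\tAA=T\tGT\t1|0\t0|0\t0|1
1\t309\trs3\tG\tA,T\t.\tPASS\tAA=G\tGT\t0|1\t0|2\t0|0
1\t410\trs4\tT\tC\t.\tPASS\tAA=.\tGT\t0|0\t1|0\t0|0
1\t502\trs5\tAT\tA\t.\tPASS\tAA=-\tGT\t1|1\t0|0\t1|0
"""

TOY_PANEL = """\
S1\tYRI\tAFR
S2\tCEU\tEUR
S3\tCHB\tASN
"""

TOY_ARCHAIC_VCF = """\
##fileformat=VCFv4.1
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tARCHAIC
1\t101\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1
1\t205\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0
1\t410\trs4\tT\tC\t.\tPASS\t.\tGT\t0/1
"""


def generate_toy_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the hand-written toy VCF/panel/archaic files to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "toy.vcf",
        "panel": outdir / "toy_panel.tsv",
        "archaic_vcf": outdir / "toy_archaic.vcf",
    }
    paths["vcf"].write_text(TOY_VCF)
    paths["panel"].write_text(TOY_PANEL)
    paths["archaic_vcf"].write_text(TOY_ARCHAIC_VCF)
    return paths
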