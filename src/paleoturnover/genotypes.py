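"""Genotype tables, EIGENSTRAT/VCF IO and sample/site quality control.

Dosages count the ALT allele (0/1/2), with ``MISSING = -1``.  Pseudo-haploid
samples carry only 0/2 calls (a single sampled allele, doubled).  All
operations are pure: they return new objects and never mutate inputs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SiteRecord",
    "SampleMeta",
    "GenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "filter_sites",
    "qc_samples",
    "read_sample_meta_csv",
    "write_sample_meta_csv",
]

MISSING = -1

_TRANSITIONS = {frozenset(("C", "T")), frozenset(("G", "A"))}


def is_transversion(ref: str, alt: str) -> bool:
    return frozenset((ref.upper(), alt.upper())) not in _TRANSITIONS


@dataclass(frozen=True)
class SiteRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float = 0.0
    info_score: float = 1.0
    site_id: str = ""

    @property
    def is_transversion(self) -> bool:
        return is_transversion(self.ref, self.alt)

    @property
    def name(self) -> str:
        return self.site_id or f"{self.chrom}_{self.pos}"


@dataclass(frozen=True)
class SampleMeta:
    id: str
    coverage: float
    mean_gp: float
    contamination: float
    date_mid: float | None = None
    group_label: str | None = None
    kin_pairs: tuple = ()  # of (other_id, degree)

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError(f"{self.id}: coverage must be >= 0")
        if not (0.0 <= self.mean_gp <= 1.0):
            raise ValueError(f"{self.id}: mean_gp must be in [0, 1]")
        if not (0.0 <= self.contamination <= 1.0):
            raise ValueError(f"{self.id}: contamination must be in [0, 1]")


@dataclass
class GenotypeTable:
    """Sites x samples ALT-dosage matrix with per-sample ploidy flags."""

    samples: list[str]
    sites: list[SiteRecord]
    dosages: np.ndarray  # (n_sites, n_samples) int8, MISSING = -1
    pseudo_haploid: np.ndarray | None = None  # bool per sample

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != (n_sites={len(self.sites)}, "
                f"n_samples={len(self.samples)})"
            )
        if self.pseudo_haploid is None:
            self.pseudo_haploid = np.zeros(len(self.samples), dtype=bool)
        self.pseudo_haploid = np.asarray(self.pseudo_haploid, dtype=bool)
        bad = ~np.isin(self.dosages, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        ph = self.pseudo_haploid
        if ph.any() and np.any(self.dosages[:, ph] == 1):
            cols = np.flatnonzero(ph)
            offenders = [self.samples[j] for j in cols if np.any(self.dosages[:, j] == 1)]
            raise ValueError(f"pseudo-haploid samples carry heterozygous calls: {offenders}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def alt_freqs(self) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing calls (NaN if none)."""
        dos = self.dosages.astype(float)
        obs = dos != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs.any(axis=1), np.where(obs, dos, 0.0).sum(axis=1) / (2.0 * obs.sum(axis=1)), np.nan)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeTable(
            samples=list(self.samples),
            sites=[s for s, m in zip(self.sites, mask) if m],
            dosages=self.dosages[mask].copy(),
            pseudo_haploid=self.pseudo_haploid.copy(),
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeTable":
        index = {s: j for j, s in enumerate(self.samples)}
        unknown = [i for i in ids if i not in index]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        cols = [index[i] for i in ids]
        return GenotypeTable(
            samples=list(ids),
            sites=list(self.sites),
            dosages=self.dosages[:, cols].copy(),
            pseudo_haploid=self.pseudo_haploid[cols].copy(),
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT triplet IO
#
# geno: one row per site, one digit per sample = count of REFERENCE alleles
#       (9 = missing); converted to/from ALT dosage on the fly.
# snp:  id chrom genetic_pos physical_pos ref alt
# ind:  id sex group
# ---------------------------------------------------------------------------

def _eigenstrat_paths(prefix) -> tuple[Path, Path, Path]:
    p = Path(prefix)
    return p.with_suffix(".geno"), p.with_suffix(".snp"), p.with_suffix(".ind")


def write_eigenstrat(table: GenotypeTable, prefix) -> None:
    geno_p, snp_p, ind_p = _eigenstrat_paths(prefix)
    with open(ind_p, "w") as fh:
        for s, ph in zip(table.samples, table.pseudo_haploid):
            group = "PSEUDOHAPLOID" if ph else "DIPLOID"
            fh.write(f"{s}\tU\t{group}\n")
    with open(snp_p, "w") as fh:
        for s in table.sites:
            fh.write(f"{s.name}\t{s.chrom}\t0.0\t{s.pos}\t{s.ref}\t{s.alt}\n")
    with open(geno_p, "w") as fh:
        for row in table.dosages:
            chars = np.where(row == MISSING, 9, 2 - row.astype(int))
            fh.write("".join(str(c) for c in chars) + "\n")


def read_eigenstrat(prefix) -> GenotypeTable:
    geno_p, snp_p, ind_p = _eigenstrat_paths(prefix)
    samples: list[str] = []
    pseudo: list[bool] = []
    with open(ind_p) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{ind_p}: line {lineno}: expected 3 columns")
            samples.append(parts[0])
            pseudo.append(parts[2] == "PSEUDOHAPLOID")
    sites: list[SiteRecord] = []
    with open(snp_p) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(f"{snp_p}: line {lineno}: expected 6 columns")
            try:
                pos = int(parts[3])
            except ValueError:
                raise ValueError(f"{snp_p}: line {lineno}: bad position {parts[3]!r}") from None
            sites.append(SiteRecord(chrom=parts[1], pos=pos, ref=parts[4], alt=parts[5], site_id=parts[0]))
    rows = []
    with open(geno_p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != len(samples) or not set(line) <= set("0129"):
                raise ValueError(f"{geno_p}: line {lineno}: malformed genotype row")
            ref_counts = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            dos = np.where(ref_counts == 9, MISSING, 2 - ref_counts.astype(int))
            rows.append(dos)
    if len(rows) != len(sites):
        raise ValueError(f"{geno_p}: {len(rows)} genotype rows but {len(sites)} snp records")
    dosages = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    table = GenotypeTable(samples, sites, dosages, np.array(pseudo))
    return _with_observed_maf(table)


def _with_observed_maf(table: GenotypeTable) -> GenotypeTable:
    freqs = table.alt_freqs()
    sites = [
        replace(s, maf=float(min(f, 1.0 - f)) if np.isfinite(f) else 0.0)
        for s, f in zip(table.sites, freqs)
    ]
    return GenotypeTable(table.samples, sites, table.dosages, table.pseudo_haploid)


# ---------------------------------------------------------------------------
# VCF IO (GT field only; pseudo-haploid samples written/read as haploid GTs)
# ---------------------------------------------------------------------------

def write_vcf(table: GenotypeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=IS,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in table.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        for site, row in zip(table.sites, table.dosages):
            gts = []
            for dos, ph in zip(row, table.pseudo_haploid):
                if ph:
                    gts.append("." if dos == MISSING else str(dos // 2))
                elif dos == MISSING:
                    gts.append("./.")
                else:
                    gts.append(["0/0", "0/1", "1/1"][dos])
            info = f"MAF={site.maf:.6g};IS={site.info_score:.6g}"
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.name}\t{site.ref}\t{site.alt}\t.\t.\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> GenotypeTable:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    sites: list[SiteRecord] = []
    rows: list[np.ndarray] = []
    pseudo = np.zeros(len(samples), dtype=bool)
    saw_maf = False
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"{path}: {rec.chrom}:{rec.pos}: only biallelic sites supported")
        maf = float(rec.info["MAF"]) if "MAF" in rec.info else None
        if maf is not None:
            saw_maf = True
        info_score = float(rec.info["IS"]) if "IS" in rec.info else 1.0
        dos = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                dos[j] = MISSING
            elif len(gt) == 1:
                pseudo[j] = True
                dos[j] = 2 * int(gt[0])
            else:
                if any(a is None for a in gt):
                    dos[j] = MISSING
                else:
                    dos[j] = int(sum(gt))
        sites.append(
            SiteRecord(
                chrom=str(rec.chrom),
                pos=int(rec.pos),
                ref=str(rec.ref),
                alt=str(rec.alts[0]),
                maf=maf if maf is not None else 0.0,
                info_score=info_score,
                site_id=str(rec.id) if rec.id else "",
            )
        )
        rows.append(dos)
    vf.close()
    dosages = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    table = GenotypeTable(samples, sites, dosages, pseudo)
    if not saw_maf:
        table = _with_observed_maf(table)
    return table


def read_genotypes(path, format: str = "eigenstrat") -> GenotypeTable:
    if format == "eigenstrat":
        return read_eigenstrat(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(table: GenotypeTable, path, format: str = "eigenstrat") -> None:
    if format == "eigenstrat":
        write_eigenstrat(table, path)
    elif format == "vcf":
        write_vcf(table, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_sites(
    g: GenotypeTable,
    min_maf: float = 0.0,
    min_info: float = 0.0,
    transversions_only: bool = False,
) -> GenotypeTable:
    """Keep sites with maf > min_maf, info_score > min_info and (optionally)
    transversion allele pairs only.  Strict inequalities, order preserved.
    """
    for name, v in (("min_maf", min_maf), ("min_info", min_info)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    mask = np.ones(g.n_sites, dtype=bool)
    if min_maf > 0:
        mask &= np.array([s.maf > min_maf for s in g.sites])
    if min_info > 0:
        mask &= np.array([s.info_score > min_info for s in g.sites])
    if transversions_only:
        mask &= np.array([s.is_transversion for s in g.sites])
    if not mask.any():
        warnings.warn("filter_sites retained zero sites", stacklevel=2)
    return g.subset_sites(mask)


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def qc_samples(
    meta: Sequence[SampleMeta],
    min_coverage: float = 0.1,
    min_gp: float = 0.98,
    max_contamination: float = 0.05,
    max_kin_degree: int = 2,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Exclude samples failing any hard threshold, then resolve close-kin
    pairs by removing the lower-coverage member until none remain.

    Thresholds are strict, matching the printed rules: excluded when
    coverage < min_coverage, mean_gp < min_gp or contamination >
    max_contamination; boundary values are retained.  Coverage ties in the
    kin step remove the lexicographically larger id (deterministic).

    Returns (retained ids in input order, [(excluded id, reason), ...]).
    """
    by_id = {m.id: m for m in meta}
    if len(by_id) != len(meta):
        raise ValueError("duplicate sample ids in metadata")

    exclusions: list[tuple[str, str]] = []
    surviving: list[str] = []
    for m in meta:
        reasons = []
        if m.coverage < min_coverage:
            reasons.append(f"coverage<{min_coverage}")
        if m.mean_gp < min_gp:
            reasons.append(f"mean_gp<{min_gp}")
        if m.contamination > max_contamination:
            reasons.append(f"contamination>{max_contamination}")
        if reasons:
            exclusions.append((m.id, ";".join(reasons)))
        else:
            surviving.append(m.id)

    # canonical symmetric set of close-kin pairs among survivors
    def live_pairs(current: set[str]) -> list[tuple[str, str]]:
        pairs = set()
        for sid in current:
            for other, degree in by_id[sid].kin_pairs:
                if degree <= max_kin_degree and other in current and other != sid:
                    pairs.add(tuple(sorted((sid, other))))
        return sorted(pairs)

    current = set(surviving)
    while True:
        pairs = live_pairs(current)
        if not pairs:
            break
        a, b = pairs[0]
        ca, cb = by_id[a].coverage, by_id[b].coverage
        if ca < cb:
            drop, keep = a, b
        elif cb < ca:
            drop, keep = b, a
        else:  # tie: remove lexicographically larger id
            drop, keep = max(a, b), min(a, b)
        exclusions.append((drop, f"kin:{keep}"))
        current.discard(drop)

    retained = [sid for sid in surviving if sid in current]
    return retained, exclusions


# ---------------------------------------------------------------------------
# Metadata CSV IO
#
# Header contract: id, coverage, mean_gp, contamination[, date_mid,
# group_label, kin]; `kin` packs pairs as "other:degree" joined by "|".
# ---------------------------------------------------------------------------

def read_sample_meta_csv(path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    required = ["id", "coverage", "mean_gp", "contamination"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        kin: tuple = ()
        if "kin" in df.columns and pd.notna(row.get("kin")) and str(row["kin"]).strip():
            kin = tuple(
                (part.split(":")[0], int(part.split(":")[1]))
                for part in str(row["kin"]).split("|")
            )
        out.append(
            SampleMeta(
                id=str(row["id"]),
                coverage=float(row["coverage"]),
                mean_gp=float(row["mean_gp"]),
                contamination=float(row["contamination"]),
                date_mid=float(row["date_mid"]) if "date_mid" in df.columns and pd.notna(row.get("date_mid")) else None,
                group_label=str(row["group_label"]) if "group_label" in df.columns and pd.notna(row.get("group_label")) else None,
                kin_pairs=kin,
            )
        )
    return out


def write_sample_meta_csv(meta: Iterable[SampleMeta], path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "id": m.id,
                "coverage": m.coverage,
                "mean_gp": m.mean_gp,
                "contamination": m.contamination,
                "date_mid": m.date_mid,
                "group_label": m.group_label,
                "kin": "|".join(f"{o}:{d}" for o, d in m.kin_pairs),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
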