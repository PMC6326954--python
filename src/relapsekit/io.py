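"""Readers and writers for standard genotype formats.

VCF 4.2 is read through cyvcf2; PLINK 1.9 .bed/.bim/.fam triplets (SNP-major)
and tab-separated dosage tables are handled directly.  All writers emit files
the corresponding loader reproduces bit-identically (round-trip contract).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    CohortMetadata,
    DosageTable,
    GenotypeMatrix,
    VariantRecord,
)
from .simulate import SimTruth

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1.9, SNP-major

# 2-bit PLINK codes, A1 = ALT: 00 hom A1 (dosage 2), 01 missing,
# 10 het, 11 hom A2 (dosage 0)
_DOSAGE_TO_BED = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_BED_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write an uncompressed VCF 4.2 with GT:GQ:DP per call."""
    path = Path(path)
    has_gq = gm.call_gq is not None
    has_dp = gm.call_dp is not None
    fmt_keys = ["GT"] + (["GQ"] if has_gq else []) + (["DP"] if has_dp else [])
    fmt = ":".join(fmt_keys)

    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(v.chrom for v in gm.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_gq:
        lines.append(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">'
        )
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )

    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, v in enumerate(gm.variants):
        cells = []
        for i in range(gm.n_samples):
            g = MISSING if gm.missing[i, j] else int(gm.dosages[i, j])
            parts = [gt_strings[g]]
            if has_gq:
                parts.append(str(int(gm.call_gq[i, j])))
            if has_dp:
                parts.append(str(int(gm.call_dp[i, j])))
            cells.append(":".join(parts))
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{','.join(v.alt)}\t.\tPASS\t.\t"
            f"{fmt}\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids in VCF header")

    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    any_gq = any_dp = False

    for rec_no, rec in enumerate(vcf):
        try:
            variants.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    ref=rec.REF,
                    alt=tuple(rec.ALT),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec_no + 1}: {exc}") from exc
        # count of non-REF alleles per sample; -1 where any allele unknown
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, geno in enumerate(rec.genotypes):
            alleles = geno[:-1]
            if any(a < 0 for a in alleles):
                continue
            col[i] = sum(1 for a in alleles if a > 0)
        dosage_cols.append(col)

        for key, cols, flag in (("GQ", gq_cols, "gq"), ("DP", dp_cols, "dp")):
            try:
                vals = rec.format(key)
            except KeyError:
                vals = None
            if vals is not None:
                if key == "GQ":
                    any_gq = True
                else:
                    any_dp = True
                cols.append(np.where(vals[:, 0] < 0, 0, vals[:, 0]).astype(np.int32))
            else:
                cols.append(np.zeros(len(sample_ids), dtype=np.int32))

    if not variants:
        raise ValueError(f"{path}: no variant records")
    dosages = np.stack(dosage_cols, axis=1)
    return GenotypeMatrix(
        sample_ids,
        variants,
        dosages,
        missing=dosages == MISSING,
        call_gq=np.stack(gq_cols, axis=1) if any_gq else None,
        call_dp=np.stack(dp_cols, axis=1) if any_dp else None,
    )


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> Path:
    """Write a PLINK 1.9 .bed/.bim/.fam triplet (SNP-major, A1 = ALT)."""
    prefix = Path(prefix)
    non_biallelic = [v.id for v in gm.variants if not v.is_biallelic]
    if non_biallelic:
        raise ValueError(
            "PLINK output requires biallelic variants; offending: "
            + ", ".join(non_biallelic[:5])
        )

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt[0]}\t{v.ref}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in gm.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")

    n = gm.n_samples
    n_bytes = (n + 3) // 4
    codes = np.empty(gm.shape, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_BED.items():
        codes[gm.dosages == dosage] = code
    codes[gm.missing] = _DOSAGE_TO_BED[MISSING]

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((gm.n_variants, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.tobytes())
    return prefix


def _load_plink(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    sample_ids = fam["iid"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{prefix}.fam: duplicate sample ids")
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1.9 bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != m * n_bytes:
        raise ValueError(
            f"{prefix}.bed: expected {m * n_bytes} data bytes, found {len(body)}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _BED_TO_DOSAGE[codes[:, :n]].T  # A1 (= ALT) allele count

    variants = [
        VariantRecord(r.chrom, int(r.pos), r.id, ref=r.a2, alt=(r.a1,))
        for r in bim.itertuples()
    ]
    return GenotypeMatrix(sample_ids, variants, dosages, missing=dosages == MISSING)


# ---------------------------------------------------------------------------
# dosage tables (long TSV)

_DOSAGE_COLS = [
    "sample_id",
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "p0",
    "p1",
    "p2",
    "dosage",
    "sd",
]


def write_dosage_table(table: DosageTable, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for j, v in enumerate(table.variants):
        for i, s in enumerate(table.sample_ids):
            rows.append(
                (
                    s, v.id, v.chrom, v.pos, v.ref, v.alt[0],
                    table.probs[i, j, 0], table.probs[i, j, 1], table.probs[i, j, 2],
                    table.dosage[i, j], table.sd[i, j],
                )
            )
    pd.DataFrame(rows, columns=_DOSAGE_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def load_dosage_table(path: str | Path) -> DosageTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing_cols = set(_DOSAGE_COLS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: dosage table missing columns {sorted(missing_cols)}")
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    var_rows = df.drop_duplicates("variant_id")
    variants = [
        VariantRecord(str(r.chrom), int(r.pos), str(r.variant_id), str(r.ref), (str(r.alt),))
        for r in var_rows.itertuples()
    ]
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    v_idx = {v.id: j for j, v in enumerate(variants)}
    n, m = len(sample_ids), len(variants)
    probs = np.zeros((n, m, 3))
    dosage = np.zeros((n, m))
    sd = np.zeros((n, m))
    ii = df["sample_id"].map(s_idx).to_numpy()
    jj = df["variant_id"].map(v_idx).to_numpy()
    probs[ii, jj, 0] = df["p0"]
    probs[ii, jj, 1] = df["p1"]
    probs[ii, jj, 2] = df["p2"]
    dosage[ii, jj] = df["dosage"]
    sd[ii, jj] = df["sd"]
    return DosageTable(sample_ids, variants, probs, dosage, sd)


def load_genotypes(
    path: str | Path, format: Literal["vcf", "plink", "dosage"] = "vcf"
) -> GenotypeMatrix | DosageTable:
    """Load genotypes from VCF, a PLINK prefix, or a dosage TSV."""
    path = Path(path)
    if format == "vcf":
        if not path.exists():
            raise FileNotFoundError(path)
        return _load_vcf(path)
    if format == "plink":
        for ext in (".bed", ".bim", ".fam"):
            if not path.with_suffix(ext).exists():
                raise FileNotFoundError(path.with_suffix(ext))
        return _load_plink(path)
    if format == "dosage":
        if not path.exists():
            raise FileNotFoundError(path)
        return load_dosage_table(path)
    raise ValueError(f"unknown genotype format: {format!r}")


# ---------------------------------------------------------------------------
# metadata / prediction sets / truth sidecars


def write_metadata(meta: CohortMetadata, path: str | Path) -> Path:
    path = Path(path)
    table = meta.table.copy()
    if meta.pcs is not None:
        for k in range(meta.pcs.shape[1]):
            table[f"pc{k + 1}"] = meta.pcs[:, k]
    table.to_csv(path, sep="\t", index=True, index_label="sample_id")
    return path


def load_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    pc_cols = [c for c in df.columns if c.startswith("pc") and c[2:].isdigit()]
    pcs = df[pc_cols].to_numpy() if pc_cols else None
    return CohortMetadata(df.drop(columns=pc_cols), pcs)


def write_sim_truth(truth: SimTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(truth), indent=2) + "\n")
    return path


def load_sim_truth(path: str | Path) -> SimTruth:
    return SimTruth(**json.loads(Path(path).read_text()))
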