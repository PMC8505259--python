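"""PLINK fileset readers and writers (text .ped/.map and binary .bed/.bim/.fam).

Both dialects round-trip the dosage matrix, sample identifiers and variant
order exactly.  Genotypes count the A1 (alternate/effect) allele.  The text
dialect does not declare alleles, so the reader recovers A1 as the
lexicographically smaller of the two observed alleles (a variant observed
with a single allele is taken as monomorphic for A2); filesets written by
:func:`write_plink` satisfy this convention because the simulator always
uses A1 < A2.

Binary .bed files are SNP-major with the standard 2-bit coding
(00 = hom A1, 01 = missing, 10 = het, 11 = hom A2), least-significant bits
first within a byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage code -> 2-bit bed code (counting A1)
_DOSAGE_TO_BED = np.array([3, 2, 0, 1], dtype=np.uint8)  # index by dosage, -1 -> last
_BED_TO_DOSAGE = np.full(4, -1, dtype=np.int8)
_BED_TO_DOSAGE[0] = 2  # hom A1
_BED_TO_DOSAGE[2] = 1  # het
_BED_TO_DOSAGE[3] = 0  # hom A2
_BED_TO_DOSAGE[1] = -1  # missing


class PlinkParseError(ValueError):
    """Malformed PLINK file; the message names the offending file and record."""


def _sex_codes(samples: pd.DataFrame) -> np.ndarray:
    if "sex" in samples.columns:
        return samples["sex"].fillna(0).astype(int).to_numpy()
    return np.zeros(len(samples), dtype=int)


def _phenotype_codes(samples: pd.DataFrame) -> np.ndarray:
    if "diagnosis" in samples.columns:
        mapping = {"patient": 2, "healthy": 1}
        return samples["diagnosis"].map(mapping).fillna(-9).astype(int).to_numpy()
    return np.full(len(samples), -9, dtype=int)


def write_plink(cohort: Cohort, prefix: str | Path, dialect: str = "binary") -> None:
    """Write a cohort as a PLINK fileset with the given path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "binary":
        _write_binary(cohort, prefix)
    elif dialect == "text":
        _write_text(cohort, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'text' or 'binary')")


def read_plink(prefix: str | Path) -> Cohort:
    """Read a PLINK fileset, auto-detecting the dialect from the files present."""
    prefix = Path(prefix)
    if prefix.with_suffix(prefix.suffix + ".bed").exists():
        return _read_binary(prefix)
    if prefix.with_suffix(prefix.suffix + ".ped").exists():
        return _read_text(prefix)
    raise FileNotFoundError(f"no .bed or .ped file found for prefix {prefix}")


# --- binary dialect ---

def _write_binary(cohort: Cohort, prefix: Path) -> None:
    v = cohort.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(prefix.suffix + ".bim"), sep="\t", header=False,
               index=False)
    s = cohort.samples
    fam = pd.DataFrame(
        {
            "fid": s["fid"],
            "iid": s["iid"],
            "pat": 0,
            "mat": 0,
            "sex": _sex_codes(s),
            "pheno": _phenotype_codes(s),
        }
    )
    fam.to_csv(prefix.with_suffix(prefix.suffix + ".fam"), sep="\t", header=False,
               index=False)

    g = cohort.genotypes  # (n, m) int8 with -1 missing
    n, m = g.shape
    codes = _DOSAGE_TO_BED[g]  # -1 indexes the trailing (missing) entry
    n_pad = (-n) % 4
    if n_pad:
        codes = np.vstack([codes, np.zeros((n_pad, m), dtype=np.uint8)])
    codes = codes.T.reshape(m, -1, 4)  # SNP-major, 4 samples per byte
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(prefix.suffix + ".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())


def _read_binary(prefix: Path) -> Cohort:
    bim_path = prefix.with_suffix(prefix.suffix + ".bim")
    fam_path = prefix.with_suffix(prefix.suffix + ".fam")
    bed_path = prefix.with_suffix(prefix.suffix + ".bed")
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"id": str, "a1": str, "a2": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != BED_MAGIC:
        raise PlinkParseError(f"{bed_path}: bad magic number (not a SNP-major .bed)")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * m:
        raise PlinkParseError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for "
            f"{n} samples x {m} variants, found {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    two_bit = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, -1)[:, :n]
    geno = _BED_TO_DOSAGE[two_bit].T.astype(np.int8)

    variants = pd.DataFrame(
        {"chrom": bim["chrom"], "id": bim["id"], "pos": bim["pos"],
         "a1": bim["a1"], "a2": bim["a2"]}
    )
    samples = pd.DataFrame(
        {
            "fid": fam["fid"],
            "iid": fam["iid"],
            "sex": fam["sex"].astype(np.int8),
            "diagnosis": fam["pheno"].map({2: "patient", 1: "healthy"}).fillna(
                "unknown"
            ),
        }
    )
    return Cohort(np.ascontiguousarray(geno), variants, samples)


# --- text dialect ---

def _write_text(cohort: Cohort, prefix: Path) -> None:
    v = cohort.variants
    pd.DataFrame(
        {"chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"]}
    ).to_csv(prefix.with_suffix(prefix.suffix + ".map"), sep="\t", header=False,
             index=False)

    a1 = v["a1"].to_numpy().astype(str)
    a2 = v["a2"].to_numpy().astype(str)
    g = cohort.genotypes
    sex = _sex_codes(cohort.samples)
    pheno = _phenotype_codes(cohort.samples)
    # allele pair per dosage code: 0 -> a2 a2, 1 -> a1 a2, 2 -> a1 a1, -1 -> 0 0
    with open(prefix.with_suffix(prefix.suffix + ".ped"), "w") as fh:
        for i in range(g.shape[0]):
            row = g[i]
            first = np.where(row >= 1, a1, a2)
            second = np.where(row == 2, a1, a2)
            first = np.where(row < 0, "0", first)
            second = np.where(row < 0, "0", second)
            fields = [
                str(cohort.samples["fid"].iat[i]),
                str(cohort.samples["iid"].iat[i]),
                "0",
                "0",
                str(sex[i]),
                str(pheno[i]),
            ]
            pairs = np.empty(2 * len(row), dtype=object)
            pairs[0::2] = first
            pairs[1::2] = second
            fh.write(" ".join(fields) + " " + " ".join(pairs) + "\n")


def _read_text(prefix: Path) -> Cohort:
    map_path = prefix.with_suffix(prefix.suffix + ".map")
    ped_path = prefix.with_suffix(prefix.suffix + ".ped")
    vmap = pd.read_csv(map_path, sep=r"\s+", header=None,
                       names=["chrom", "id", "cm", "pos"], dtype={"id": str})
    m = len(vmap)

    rows = []
    meta = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * m} for {m} variants in {map_path}"
                )
            meta.append(fields[:6])
            rows.append(fields[6:])
    alleles = np.array(rows, dtype="U8").reshape(len(rows), m, 2)

    n = len(rows)
    geno = np.full((n, m), -1, dtype=np.int8)
    a1_out = np.empty(m, dtype=object)
    a2_out = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        observed = np.unique(col[col != "0"])
        if observed.size > 2:
            raise PlinkParseError(
                f"{ped_path}: variant {vmap['id'].iat[j]} (column {j + 1}) has "
                f"{observed.size} distinct alleles"
            )
        if observed.size == 0:
            a1, a2 = "0", "0"
        elif observed.size == 1:
            a1, a2 = "0", observed[0]
        else:
            a1, a2 = sorted(observed)
        a1_out[j], a2_out[j] = a1, a2
        valid = (col != "0").all(axis=1)
        geno[valid, j] = (col[valid] == a1).sum(axis=1)
    samples = pd.DataFrame(
        meta, columns=["fid", "iid", "pat", "mat", "sex", "pheno"]
    )
    pheno = pd.to_numeric(samples["pheno"], errors="coerce")
    samples_out = pd.DataFrame(
        {
            "fid": samples["fid"],
            "iid": samples["iid"],
            "sex": pd.to_numeric(samples["sex"], errors="coerce").fillna(0).astype(
                np.int8
            ),
            "diagnosis": pheno.map({2.0: "patient", 1.0: "healthy"}).fillna("unknown"),
        }
    )
    variants = pd.DataFrame(
        {"chrom": vmap["chrom"], "id": vmap["id"], "pos": vmap["pos"],
         "a1": a1_out, "a2": a2_out}
    )
    return Cohort(geno, variants, samples_out)


# --- tabular sidecars ---

def write_sample_table(cohort: Cohort, path: str | Path) -> None:
    """Sample/phenotype table as TSV (one row per sample, documented columns)."""
    cohort.samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tables(cohort: Cohort, variant_path: str | Path,
                       sample_path: str | Path) -> None:
    """Simulation ground truth as two TSVs (per-variant and per-sample)."""
    if cohort.truth is None:
        raise ValueError("cohort carries no simulation truth")
    t = cohort.truth
    pd.DataFrame(
        {"id": cohort.variants["id"], "variant_class": t.variant_class}
    ).to_csv(variant_path, sep="\t", index=False)
    per_sample = pd.DataFrame(
        {
            "iid": cohort.samples["iid"],
            "drug_liability": t.drug_liability,
            "disease_liability": t.disease_liability,
        }
    )
    per_sample = pd.concat(
        [per_sample, t.onsets.add_prefix("onset_")], axis=1
    )
    per_sample.to_csv(sample_path, sep="\t", index=False)
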