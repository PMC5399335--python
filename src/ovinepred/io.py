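"""File I/O: PLINK BED/BIM/FAM, phenotype/pedigree TSVs, relationship matrices.

The BED codec implements the standard PLINK 1 binary layout: a 3-byte magic
header ``0x6c 0x1b 0x01`` (SNP-major), then one byte per four individuals per
SNP, two bits per genotype with codes 00 = homozygous A1 (dosage 2 of the
counted allele), 01 = missing, 10 = heterozygous, 11 = homozygous A2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ovinepred.containers import MISSING, GenotypeMatrix, Pedigree

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 2-bit code -> dosage of A1; 1 is the missing code
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam in SNP-major PLINK 1 format."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.calls.shape

    bim = pd.DataFrame(
        {
            "chrom": geno.chrom,
            "snp": geno.snp_ids,
            "cm": 0.0,
            "pos": geno.pos,
            "a1": geno.counted_allele,
            "a2": "B" if geno.counted_allele == "A" else "A",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {"fid": geno.ids, "iid": geno.ids, "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    # map dosages to 2-bit codes (SNP-major)
    calls = geno.calls
    codes = np.empty_like(calls, dtype=np.uint8)
    codes[calls == 2] = 0
    codes[calls == MISSING] = 1
    codes[calls == 1] = 2
    codes[calls == 0] = 3

    n_bytes = (n + 3) // 4
    padded = np.zeros((m, 4 * n_bytes), dtype=np.uint8)
    padded[:, :n] = codes.T  # pad code 0; harmless, only first n decoded
    shaped = padded.reshape(m, n_bytes, 4)
    packed = (
        shaped[:, :, 0]
        | (shaped[:, :, 1] << 2)
        | (shaped[:, :, 2] << 4)
        | (shaped[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 BED file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise ValueError(f"unexpected BED payload size for {n} samples x {m} SNPs")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    calls = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(
        ids=fam["iid"].to_numpy(dtype=object),
        snp_ids=bim["snp"].to_numpy(dtype=object),
        chrom=bim["chrom"].to_numpy(dtype=object),
        pos=bim["pos"].to_numpy(),
        calls=calls,
        counted_allele=str(bim["a1"].iloc[0]) if m else "A",
    )


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    t = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    t["sire"] = t["sire"].fillna("")
    t["dam"] = t["dam"].fillna("")
    return Pedigree(table=t)


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})


def write_relationship_matrix(values: np.ndarray, ids, prefix: str | Path) -> None:
    """Binary float64 square matrix at ``prefix``.grm.bin + ids sidecar TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.asarray(values, dtype=np.float64).tofile(str(prefix) + ".grm.bin")
    pd.DataFrame({"id": list(ids)}).to_csv(str(prefix) + ".grm.ids", sep="\t", index=False)


def read_relationship_matrix(prefix: str | Path):
    ids = pd.read_csv(str(prefix) + ".grm.ids", sep="\t", dtype={"id": str})["id"].to_numpy(
        dtype=object
    )
    n = ids.size
    values = np.fromfile(str(prefix) + ".grm.bin", dtype=np.float64).reshape(n, n)
    return values, ids


def write_relationship_long(values: np.ndarray, ids, path: str | Path) -> None:
    """Long-format TSV (id1, id2, value), upper triangle including diagonal."""
    ids = list(ids)
    n = len(ids)
    iu = np.triu_indices(n)
    out = pd.DataFrame(
        {
            "id1": [ids[i] for i in iu[0]],
            "id2": [ids[j] for j in iu[1]],
            "value": values[iu],
        }
    )
    out.to_csv(path, sep="\t", index=False)
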