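"""Readers and writers for the pipeline's tabular formats.

Genotypes travel in a PLINK-.raw-style TSV (FID IID SEX then one column per
variant named ``<snp>_<effectallele>`` holding dosages 0/1/2/NA); weights,
scores, gains and results are plain TSV; anthropometry and LMS references
are CSV. Files written by the simulator carry a ``# seed=`` comment header,
which every reader skips.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, VariantWeight

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_weights",
    "write_weights",
    "read_anthro",
    "write_anthro",
    "read_lms",
    "write_lms",
    "read_labels",
]

_NA_STRINGS_DEFAULT = ("NA",)


def _read_table(path, sep):
    return pd.read_csv(path, sep=sep, comment="#", dtype=str,
                       keep_default_na=False, na_values=[])


def read_genotypes(path, na_strings=_NA_STRINGS_DEFAULT) -> GenotypeMatrix:
    """Parse a PLINK-.raw-style TSV into a GenotypeMatrix.

    The counted allele of each variant column is taken from the header
    suffix ``_<allele>``; the companion allele is read from an optional
    ``# other_alleles:`` comment line, else left as 'N'. ``na_strings``
    selects which cell values (besides an empty cell never being valid)
    are treated as missing.
    """
    path = Path(path)
    other_map = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# other_alleles:"):
                for tok in line.split(":", 1)[1].split():
                    snp, al = tok.rsplit("=", 1)
                    other_map[snp] = al
            elif not line.startswith("#"):
                break
    df = _read_table(path, sep="\t")
    required = ["FID", "IID", "SEX"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: header must start with {required}, "
                         f"got {list(df.columns[:3])}")
    var_cols = list(df.columns[3:])
    snp_ids, counted = [], []
    for c in var_cols:
        m = re.fullmatch(r"(.+)_([ACGTN])", c)
        if not m:
            raise ValueError(f"{path}: variant column {c!r} lacks an "
                             "'_<allele>' suffix")
        snp_ids.append(m.group(1))
        counted.append(m.group(2))
    n = len(df)
    dosages = np.full((n, len(var_cols)), np.nan)
    for j, c in enumerate(var_cols):
        col = df[c].to_numpy()
        for i, cell in enumerate(col):
            if cell in na_strings:
                continue
            if cell not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: line {i + 2}, column {c!r}: cell {cell!r} "
                    "is not in {0, 1, 2, NA}"
                )
            dosages[i, j] = float(cell)
    return GenotypeMatrix(
        subject_ids=df["IID"].to_numpy(dtype=object),
        variant_ids=np.array(snp_ids, dtype=object),
        dosages=dosages,
        counted_alleles=np.array(counted, dtype=object),
        other_alleles=np.array([other_map.get(s, "N") for s in snp_ids], dtype=object),
        sex=df["SEX"].to_numpy(dtype=object),
    )


def write_genotypes(g: GenotypeMatrix, path, seed: int | None = None) -> None:
    path = Path(path)
    header = ["FID", "IID", "SEX"] + [
        f"{s}_{a}" for s, a in zip(g.variant_ids, g.counted_alleles)
    ]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("# other_alleles: " + " ".join(
            f"{s}={a}" for s, a in zip(g.variant_ids, g.other_alleles)) + "\n")
        fh.write("\t".join(header) + "\n")
        sex = g.sex if g.sex is not None else ["0"] * g.n_subjects
        for i in range(g.n_subjects):
            cells = [str(g.subject_ids[i]), str(g.subject_ids[i]), str(sex[i])]
            for v in g.dosages[i]:
                cells.append("NA" if np.isnan(v) else str(int(v)))
            fh.write("\t".join(cells) + "\n")


def read_weights(path) -> list[VariantWeight]:
    """Weights TSV: snp, effect_allele, other_allele, beta[, eaf]."""
    df = _read_table(path, sep="\t")
    need = {"snp", "effect_allele", "other_allele", "beta"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: weights file needs columns {sorted(need)}")
    out = []
    for _, row in df.iterrows():
        eaf = None
        if "eaf" in df.columns and row["eaf"] not in ("", "NA"):
            eaf = float(row["eaf"])
        out.append(VariantWeight(row["snp"], row["effect_allele"],
                                 row["other_allele"], float(row["beta"]), eaf))
    return out


def write_weights(weights: list[VariantWeight], path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("snp\teffect_allele\tother_allele\tbeta\teaf\n")
        for w in weights:
            eaf = "NA" if w.eaf is None else f"{w.eaf:.6g}"
            fh.write(f"{w.snp_id}\t{w.effect_allele}\t{w.other_allele}\t"
                     f"{w.beta:.6g}\t{eaf}\n")


def read_anthro(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    need = {"subject_id", "sex", "age_years", "weight_kg", "height_cm"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: anthro file needs columns {sorted(need)}")
    if (df["weight_kg"] <= 0).any() or (df["height_cm"] <= 0).any():
        raise ValueError(f"{path}: non-positive weight or height")
    if (df["age_years"] < 0).any():
        raise ValueError(f"{path}: negative age")
    return df


def write_anthro(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_lms(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    need = {"sex", "age", "L", "M", "S"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: LMS file needs columns {sorted(need)}")
    if (df["M"] <= 0).any() or (df["S"] <= 0).any():
        raise ValueError(f"{path}: M and S must be positive")
    return df


def write_lms(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    need = {"subject_id", "class"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: labels file needs columns {sorted(need)}")
    return df
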