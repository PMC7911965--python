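"""Genotype dataset container and on-disk formats.

Case-control genotype data is held as an L-sample x N-SNP matrix of
minor-allele dosages (0 = homozygous major, 1 = heterozygous,
2 = homozygous minor) with a binary phenotype (0 = control, 1 = case).
Two plain-text dialects are supported:

* ``gametes_tsv`` -- tab-separated, header row of SNP names followed by a
  final ``Class`` column holding the phenotype; one row per sample.
* ``plink_raw`` -- the PLINK ``--recode A`` dialect: whitespace-separated
  with the six leading columns ``FID IID PAT MAT SEX PHENOTYPE`` (phenotype
  coded 1/2 and remapped to 0/1) followed by one dosage column per SNP.

Missing genotypes are stored as :data:`MISSING`; the tokens ``NA`` and
(for ``plink_raw``) ``-9`` map to it on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the in-memory matrix.
MISSING: int = -1

_FORMATS = ("gametes_tsv", "plink_raw")
_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class FormatError(ValueError):
    """A file does not conform to the declared genotype dialect."""


class ParseError(FormatError):
    """A field in an otherwise well-formed file is out of domain."""


@dataclass
class GenotypeDataset:
    """Sample x SNP genotype matrix with a binary case-control phenotype.

    Parameters
    ----------
    genotypes : ndarray of shape (L, N)
        Minor-allele dosages in {0, 1, 2} or :data:`MISSING`.
    phenotype : ndarray of shape (L,)
        0 for controls, 1 for cases.
    snp_names, sample_names
        Unique SNP identifiers; per-sample identifiers.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str]
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8).ravel()
        self.snp_names = [str(s) for s in self.snp_names]
        if not self.sample_names:
            self.sample_names = [f"S{i + 1}" for i in range(self.genotypes.shape[0])]
        self.sample_names = [str(s) for s in self.sample_names]

    # -- basic shape accessors ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))

    def to_frame(self) -> pd.DataFrame:
        """Genotypes plus a trailing ``Class`` column, NA for missing."""
        df = pd.DataFrame(self.genotypes, columns=self.snp_names, copy=True).astype("Int64")
        df[df == MISSING] = pd.NA
        df["Class"] = self.phenotype
        return df


def validate_dataset(ds: GenotypeDataset) -> list[str]:
    """Check every dataset invariant, returning a human-readable violation list.

    An empty list means the dataset is valid. Violations name the invariant
    and the offending coordinate; this never raises.
    """
    violations: list[str] = []
    L, N = ds.genotypes.shape
    if len(ds.phenotype) != L:
        violations.append(
            f"phenotype length {len(ds.phenotype)} != sample count {L}"
        )
    if len(ds.snp_names) != N:
        violations.append(f"snp_names length {len(ds.snp_names)} != SNP count {N}")
    if len(ds.sample_names) != L:
        violations.append(
            f"sample_names length {len(ds.sample_names)} != sample count {L}"
        )

    bad = ~np.isin(ds.genotypes, (0, 1, 2, MISSING))
    for row, col in zip(*np.nonzero(bad)):
        violations.append(
            f"genotype out of domain at sample {row + 1}, SNP {col + 1}: "
            f"{ds.genotypes[row, col]}"
        )
    bad_ph = ~np.isin(ds.phenotype, (0, 1))
    for (row,) in zip(*np.nonzero(bad_ph)):
        violations.append(
            f"phenotype out of domain at sample {row + 1}: {ds.phenotype[row]}"
        )
    seen: dict[str, int] = {}
    for j, name in enumerate(ds.snp_names):
        if name in seen:
            violations.append(
                f"duplicate SNP name {name!r} at columns {seen[name] + 1} and {j + 1}"
            )
        else:
            seen[name] = j
    return violations


def _require_valid(ds: GenotypeDataset) -> None:
    violations = validate_dataset(ds)
    if violations:
        raise ValueError("invalid dataset: " + "; ".join(violations[:5]))


def _parse_genotype_column(
    raw: pd.Series, col_name: str, missing_tokens: tuple[str, ...]
) -> np.ndarray:
    vals = raw.astype(str).str.strip()
    out = np.empty(len(vals), dtype=np.int8)
    for i, tok in enumerate(vals):
        if tok in missing_tokens:
            out[i] = MISSING
        elif tok in ("0", "1", "2"):
            out[i] = int(tok)
        else:
            raise ParseError(
                f"malformed genotype {tok!r} at row {i + 1}, column {col_name!r}"
            )
    return out


def read_dataset(path, format: str = "gametes_tsv") -> GenotypeDataset:
    """Read a genotype file and return a validated :class:`GenotypeDataset`.

    Parameters
    ----------
    path : path-like
    format : {"gametes_tsv", "plink_raw"}

    Raises
    ------
    FormatError
        Empty file, missing ``Class`` column, or malformed header.
    ParseError
        A genotype value outside {0, 1, 2, missing token}.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    try:
        sep = "\t" if format == "gametes_tsv" else r"\s+"
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no sample rows")

    if format == "gametes_tsv":
        if df.columns[-1] != "Class":
            raise FormatError(
                f"{path}: last column must be 'Class', found {df.columns[-1]!r}"
            )
        snp_cols = list(df.columns[:-1])
        geno = np.column_stack(
            [_parse_genotype_column(df[c], c, ("NA",)) for c in snp_cols]
        )
        pheno_raw = df["Class"].astype(str).str.strip()
        if not pheno_raw.isin(["0", "1"]).all():
            bad = pheno_raw[~pheno_raw.isin(["0", "1"])].iloc[0]
            raise ParseError(f"{path}: phenotype value {bad!r} not in {{0, 1}}")
        pheno = pheno_raw.astype(np.int8).to_numpy()
        samples = [f"S{i + 1}" for i in range(len(df))]
    else:  # plink_raw
        if list(df.columns[:6]) != _PLINK_META_COLS:
            raise FormatError(
                f"{path}: plink_raw header must start with {' '.join(_PLINK_META_COLS)}"
            )
        snp_cols = list(df.columns[6:])
        if not snp_cols:
            raise FormatError(f"{path}: no SNP columns")
        geno = np.column_stack(
            [_parse_genotype_column(df[c], c, ("NA", "-9")) for c in snp_cols]
        )
        pheno_raw = df["PHENOTYPE"].astype(str).str.strip()
        if not pheno_raw.isin(["1", "2"]).all():
            bad = pheno_raw[~pheno_raw.isin(["1", "2"])].iloc[0]
            raise ParseError(f"{path}: PHENOTYPE value {bad!r} not in {{1, 2}}")
        pheno = (pheno_raw.astype(np.int8) - 1).to_numpy()
        # strip the usual "_A" counted-allele suffix if uniformly present
        if all("_" in c for c in snp_cols):
            stripped = [c.rsplit("_", 1)[0] for c in snp_cols]
            if len(set(stripped)) == len(stripped):
                snp_cols = stripped
        samples = df["IID"].astype(str).tolist()

    ds = GenotypeDataset(geno, pheno, snp_cols, samples)
    _require_valid(ds)
    return ds


def write_dataset(ds: GenotypeDataset, path, format: str = "gametes_tsv"):
    """Write a dataset so that :func:`read_dataset` round-trips it exactly."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if ds.n_samples == 0 or ds.n_snps == 0:
        raise FormatError("refusing to write an empty dataset")
    _require_valid(ds)

    geno = ds.genotypes.astype(object)
    geno[ds.genotypes == MISSING] = "NA"
    if format == "gametes_tsv":
        df = pd.DataFrame(geno, columns=ds.snp_names)
        df["Class"] = ds.phenotype
        df.to_csv(path, sep="\t", index=False)
    else:
        df = pd.DataFrame(geno, columns=[f"{s}_A" for s in ds.snp_names])
        meta = pd.DataFrame(
            {
                "FID": ds.sample_names,
                "IID": ds.sample_names,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": ds.phenotype + 1,
            }
        )
        pd.concat([meta, df], axis=1).to_csv(path, sep=" ", index=False)
    return path
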