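"""Containers and readers/writers for trial phenotypes, SNP genotypes and
SE-HPLC fraction areas.

Three table kinds circulate through the pipeline:

``PhenotypeTable``
    Long-format trait observations (genotype, year, rep, trait, value).
    Evaluator scores and bench measurements both live here; for sensory
    traits the "rep" is the evaluator.
``GenotypeMatrix``
    Lines x biallelic markers, coded as allele dose {0, 1, 2} with NaN for
    missing.  Read from numeric CSV, HapMap-dialect text or a minimal VCF.
``FractionAreaTable``
    Per-sample SE-HPLC absorbance areas (mAU*min) for the SDS-extractable
    (E) and SDS-unextractable (U) fraction sets, four fractions each.

Dose convention: for HapMap and VCF input the counted allele is the major
allele observed at read time (ties broken toward the file's first/reference
allele); the choice is recorded per marker in ``GenotypeMatrix.counted_allele``
so that effect signs are reproducible.  Numeric CSV input is taken as-is.
"""

from __future__ import annotations

import io as _io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["genotype", "year", "rep", "trait", "value"]

_SNP_NAME_RE = re.compile(r"^S(?P<chrom>[^_]+)_(?P<pos>\d+)$")

#: HapMap header columns preceding the sample calls
_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


def parse_snp_name(name: str) -> tuple[str | None, int | None]:
    """Parse marker names of the form ``S<chrom>_<pos>`` into (chrom, pos).

    Returns ``(None, None)`` when the name does not follow the convention.
    """
    m = _SNP_NAME_RE.match(str(name))
    if m is None:
        return None, None
    return m.group("chrom"), int(m.group("pos"))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

class PhenotypeTable:
    """Validated long-format phenotype observations.

    Parameters
    ----------
    data
        DataFrame with columns genotype, year, rep, trait, value.
    validate
        Check invariants (finite values, unique keys) on construction.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        data = data.loc[:, PHENO_COLUMNS].copy()
        data["genotype"] = data["genotype"].astype(str)
        data["year"] = data["year"].astype(str)
        data["rep"] = data["rep"].astype(str)
        data["trait"] = data["trait"].astype(str)
        data["value"] = pd.to_numeric(data["value"], errors="raise")
        self.data = data.reset_index(drop=True)
        self.read_report: dict = {}
        if validate:
            self._validate()

    def _validate(self) -> None:
        d = self.data
        if not np.isfinite(d["value"]).all():
            bad = d.index[~np.isfinite(d["value"])].tolist()
            raise FormatError(f"non-finite trait values at rows {bad[:10]}")
        dup = d.duplicated(subset=["genotype", "year", "rep", "trait"])
        if dup.any():
            rows = d.loc[dup, ["genotype", "year", "rep", "trait"]]
            raise FormatError(
                "duplicate (genotype, year, rep, trait) keys, first: "
                f"{rows.iloc[0].to_dict()}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def years(self) -> list[str]:
        return sorted(self.data["year"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    def subset(self, trait: str) -> pd.DataFrame:
        if trait not in set(self.data["trait"]):
            raise KeyError(f"trait {trait!r} not present (have {self.traits})")
        return self.data[self.data["trait"] == trait].copy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"PhenotypeTable({len(self.data)} records, "
            f"{len(self.genotypes)} genotypes, {len(self.traits)} traits)"
        )


def read_phenotype_table(source, dialect: str = "long") -> PhenotypeTable:
    """Read a phenotype CSV in long or wide dialect.

    Wide dialect has columns genotype, year, rep plus one column per trait;
    it is melted to long form.  Rows with missing values are dropped and
    counted in ``result.read_report['n_dropped']``.
    """
    raw = pd.read_csv(source)
    if dialect == "long":
        missing = [c for c in PHENO_COLUMNS if c not in raw.columns]
        if missing:
            raise FormatError(f"long phenotype CSV lacks columns {missing}")
        long = raw[PHENO_COLUMNS].copy()
        long["value"] = pd.to_numeric(long["value"], errors="coerce")
    elif dialect == "wide":
        keys = ["genotype", "year", "rep"]
        missing = [c for c in keys if c not in raw.columns]
        if missing:
            raise FormatError(f"wide phenotype CSV lacks columns {missing}")
        trait_cols = [c for c in raw.columns if c not in keys]
        if not trait_cols:
            raise FormatError("wide phenotype CSV has no trait columns")
        long = raw.melt(id_vars=keys, value_vars=trait_cols,
                        var_name="trait", value_name="value")
        long["value"] = pd.to_numeric(long["value"], errors="coerce")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    n_before = len(long)
    long = long.dropna(subset=["value"])
    table = PhenotypeTable(long)
    table.read_report = {"n_dropped": n_before - len(long), "dialect": dialect}
    return table


def write_phenotype_table(table: PhenotypeTable, path) -> None:
    table.to_csv(path)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Lines x markers allele-dose matrix.

    Attributes
    ----------
    line_ids
        Line (genotype) identifiers, row order of ``calls``.
    markers
        DataFrame with columns name, chromosome, position (1-based bp).
    calls
        float array, shape (n_lines, n_markers); values in {0, 1, 2} or NaN.
    counted_allele
        Optional per-marker record of which allele dose 2 counts
        (e.g. ``("A", "G")`` = counted/other), parallel to ``markers``.
    read_report
        Parser bookkeeping (e.g. skipped multiallelic record count).
    """

    line_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    counted_allele: list[tuple[str, str]] | None = None
    read_report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        n_lines, n_markers = self.calls.shape
        if len(self.line_ids) != n_lines:
            raise FormatError(
                f"{len(self.line_ids)} line ids but {n_lines} call rows")
        if len(self.markers) != n_markers:
            raise FormatError(
                f"{len(self.markers)} markers but {n_markers} call columns")
        if self.markers["name"].duplicated().any():
            dups = self.markers.loc[self.markers["name"].duplicated(), "name"]
            raise FormatError(f"duplicate marker names: {list(dups[:5])}")
        pos = self.markers["position"]
        if (pos.dropna() < 0).any():
            raise FormatError("negative marker positions")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise FormatError("calls must be 0/1/2 or missing (NaN)")
        self.markers = self.markers.reset_index(drop=True)

    # -- derived -----------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_names(self) -> list[str]:
        return self.markers["name"].tolist()

    def dose_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.line_ids,
                            columns=self.marker_names)

    def marker_index(self, name: str) -> int:
        idx = self.markers.index[self.markers["name"] == name]
        if len(idx) == 0:
            raise KeyError(f"marker {name!r} not in matrix")
        return int(idx[0])

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        counted = (None if self.counted_allele is None
                   else [self.counted_allele[i] for i in np.flatnonzero(keep)]
                   if keep.dtype == bool
                   else [self.counted_allele[i] for i in keep])
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            markers=self.markers.loc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
            counted_allele=counted,
        )

    # -- writers -----------------------------------------------------------
    def to_numeric_csv(self, path) -> None:
        df = self.dose_frame()
        out = df.where(df.notna(), -1).astype(int)
        out.index.name = "line"
        out.to_csv(path)

    def to_hapmap(self, path) -> None:
        alleles = self.counted_allele or [("A", "G")] * self.n_markers
        rows = []
        for j, (_, mk) in enumerate(self.markers.iterrows()):
            a, b = alleles[j]
            geno_map = {0.0: b + b, 1.0: a + b, 2.0: a + a}
            calls = ["NN" if np.isnan(d) else geno_map[d]
                     for d in self.calls[:, j]]
            rows.append([mk["name"], f"{a}/{b}", mk["chromosome"],
                         int(mk["position"]), "+", "NA", "NA", "NA", "NA",
                         "NA", "NA"] + calls)
        header = _HAPMAP_META + list(self.line_ids)
        pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF; REF is the counted (major) allele."""
        alleles = self.counted_allele or [("A", "G")] * self.n_markers
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        for chrom in pd.unique(self.markers["chromosome"]):
            lines.append(f"##contig=<ID={chrom}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.line_ids))
        gt_map = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}
        for j, (_, mk) in enumerate(self.markers.iterrows()):
            ref, alt = alleles[j]
            gts = ["./." if np.isnan(d) else gt_map[d] for d in self.calls[:, j]]
            lines.append("\t".join(
                [str(mk["chromosome"]), str(int(mk["position"])), str(mk["name"]),
                 ref, alt, ".", ".", ".", "GT"] + gts))
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)


def _major_recode(dose_counted_first: np.ndarray,
                  allele_pairs: list[tuple[str, str]]
                  ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Flip per-marker dose so dose 2 counts the major allele.

    ``dose_counted_first`` counts the first allele of each pair.  Ties
    (frequency exactly 0.5) keep the first allele.
    """
    calls = dose_counted_first.astype(float)
    counted: list[tuple[str, str]] = []
    for j, (a, b) in enumerate(allele_pairs):
        col = calls[:, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(col) / 2.0
        if np.isnan(freq) or freq >= 0.5:
            counted.append((a, b))
        else:
            calls[:, j] = 2.0 - col
            counted.append((b, a))
    return calls, counted


def read_genotype_matrix(source, format: str = "numeric") -> GenotypeMatrix:
    """Read a genotype matrix from numeric CSV, HapMap text or VCF.

    Numeric CSV: first column line id, one column per marker, codes
    {0,1,2,-1}; -1 maps to missing and doses are taken as-is.  HapMap and
    VCF calls are recoded so dose counts the major allele (see module notes).
    VCF records that are not biallelic SNPs are skipped with a warning and
    counted in ``read_report['n_skipped']``.
    """
    if format == "numeric":
        return _read_numeric(source)
    if format == "hapmap":
        return _read_hapmap(source)
    if format == "vcf":
        return _read_vcf(source)
    raise ValueError(f"unknown genotype format {format!r}")


def _marker_frame(names) -> pd.DataFrame:
    parsed = [parse_snp_name(n) for n in names]
    return pd.DataFrame({
        "name": list(names),
        "chromosome": [c for c, _ in parsed],
        "position": [p for _, p in parsed],
    })


def _read_numeric(source) -> GenotypeMatrix:
    df = pd.read_csv(source, index_col=0)
    calls = df.to_numpy(dtype=float)
    bad = ~(np.isin(calls, (-1.0, 0.0, 1.0, 2.0)) | np.isnan(calls))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"invalid dose code {calls[i, j]!r} for line {df.index[i]!r}, "
            f"marker {df.columns[j]!r}")
    calls[calls == -1.0] = np.nan
    return GenotypeMatrix(
        line_ids=[str(i) for i in df.index],
        markers=_marker_frame(df.columns),
        calls=calls,
    )


def _read_hapmap(source) -> GenotypeMatrix:
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in ("rs#", "alleles", "chrom", "pos") if c not in df.columns]
    if missing:
        raise FormatError(f"HapMap text lacks columns {missing}")
    sample_cols = [c for c in df.columns if c not in _HAPMAP_META]
    if not sample_cols:
        raise FormatError("HapMap text has no sample columns")
    n_markers, n_lines = len(df), len(sample_cols)
    dose = np.full((n_lines, n_markers), np.nan)
    pairs: list[tuple[str, str]] = []
    for j, row in df.iterrows():
        try:
            a, b = row["alleles"].split("/")
        except ValueError:
            raise FormatError(
                f"marker {row['rs#']!r}: alleles field {row['alleles']!r} "
                "is not 'X/Y'") from None
        pairs.append((a, b))
        for i, col in enumerate(sample_cols):
            call = row[col]
            if call in ("NN", "N", "--", "NA") or pd.isna(call):
                continue
            if len(call) != 2 or any(ch not in (a, b) for ch in call):
                raise FormatError(
                    f"marker {row['rs#']!r}, sample {col!r}: call {call!r} "
                    f"inconsistent with alleles {a}/{b}")
            dose[i, j] = sum(ch == a for ch in call)
    calls, counted = _major_recode(dose, pairs)
    markers = pd.DataFrame({
        "name": df["rs#"].tolist(),
        "chromosome": df["chrom"].tolist(),
        "position": pd.to_numeric(df["pos"]).astype(int).tolist(),
    })
    return GenotypeMatrix(line_ids=sample_cols, markers=markers, calls=calls,
                          counted_allele=counted)


def _read_vcf(source) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(source))
    line_ids = list(vcf.samples)
    names, chroms, positions, pairs, dose_cols = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            warnings.warn(
                f"skipping non-biallelic-SNP record at {var.CHROM}:{var.POS}")
            continue
        ref_dose = np.full(len(line_ids), np.nan)
        for i, gt in enumerate(var.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue
            ref_dose[i] = (a1 == 0) + (a2 == 0)
        names.append(var.ID if var.ID not in (None, ".")
                     else f"S{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)  # 1-based per the standard
        pairs.append((var.REF, var.ALT[0]))
        dose_cols.append(ref_dose)
    if not names:
        raise FormatError("no biallelic SNP records in VCF")
    dose = np.column_stack(dose_cols)
    calls, counted = _major_recode(dose, pairs)
    markers = pd.DataFrame({"name": names, "chromosome": chroms,
                            "position": positions})
    gm = GenotypeMatrix(line_ids=line_ids, markers=markers, calls=calls,
                        counted_allele=counted)
    gm.read_report = {"n_skipped": n_skipped}
    return gm


# ---------------------------------------------------------------------------
# SE-HPLC fraction areas
# ---------------------------------------------------------------------------

FRACTION_COLUMNS = [f"{s}_F{i}" for s in ("E", "U") for i in range(1, 5)]


class FractionAreaTable:
    """Per-sample SE-HPLC absorbance areas (mAU*min).

    Columns ``E_F1..E_F4`` are the SDS-extractable fraction areas and
    ``U_F1..U_F4`` the SDS-unextractable ones; F1 = HMW polymeric protein,
    F2 = LMW glutenin polymers, F3 = gliadins, F4 = albumins/globulins.
    The index identifies the sample.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        missing = [c for c in FRACTION_COLUMNS if c not in data.columns]
        # F4 may be absent; F1-F3 are required for the ratios
        required_missing = [c for c in missing if not c.endswith("_F4")]
        if required_missing:
            raise FormatError(f"fraction table lacks columns {required_missing}")
        data = data.copy()
        for c in missing:
            data[c] = 0.0
        data = data[FRACTION_COLUMNS].astype(float)
        if validate and (data.to_numpy() < 0).any():
            raise FormatError("negative absorbance areas")
        self.data = data

    @property
    def samples(self) -> list:
        return list(self.data.index)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = out.index.name or "sample"
        out.to_csv(path)

    def __len__(self) -> int:
        return len(self.data)


def read_fraction_areas(source) -> FractionAreaTable:
    df = pd.read_csv(source, index_col=0)
    return FractionAreaTable(df)
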