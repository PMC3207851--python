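"""Tables and genotype QC.

The pipeline's central inputs are a marker map (chromosome, bp position,
marker name) and a backcross genotype matrix (plants x markers).  Each plant
of a backcross reveals one gamete of the F1: a homozygous call (``A``, two
copies of the recurrent-parent allele) means the gamete carried the recurrent
allele, a heterozygous call (``H``) means it carried the donor allele.
Missing calls are encoded ``-`` or ``NA`` on disk and ``-1`` internally.

All readers validate and reject rather than coerce; ``write . read`` is the
identity on valid files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CODE_A",
    "CODE_H",
    "CODE_MISSING",
    "MarkerMap",
    "GenotypeMatrix",
    "read_marker_map",
    "write_marker_map",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "flag_singletons",
    "write_interval_table",
    "read_interval_table",
]

#: integer genotype codes used throughout the package
CODE_A = 0  # homozygote, recurrent parent (Col/Col in a Col x (Col x Ler) cross)
CODE_H = 1  # heterozygote (Col/Ler)
CODE_MISSING = -1

_STR_OF_CODE = {CODE_A: "A", CODE_H: "H", CODE_MISSING: "-"}
_CODE_OF_STR = {"A": CODE_A, "H": CODE_H, "-": CODE_MISSING, "NA": CODE_MISSING}


class MarkerMap:
    """Ordered marker positions per chromosome.

    Parameters
    ----------
    table
        DataFrame with columns ``chrom``, ``pos`` (1-based bp) and ``marker``.
        Positions must be strictly increasing within a chromosome and marker
        names unique.  Intervals between adjacent markers are half-open
        ``[left_bp, right_bp)``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "pos", "marker"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        table = table.loc[:, ["chrom", "pos", "marker"]].reset_index(drop=True)
        table["pos"] = table["pos"].astype(np.int64)
        if table["marker"].duplicated().any():
            dupes = table.loc[table["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names: {dupes}")
        for chrom, sub in table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"marker positions not strictly increasing on {chrom}"
                )
            if pos[0] < 1:
                raise ValueError(f"non-positive marker position on {chrom}")
        self.table = table

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def marker_names(self) -> list[str]:
        return self.table["marker"].tolist()

    def positions(self, chrom) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    def markers(self, chrom) -> list[str]:
        return self.table.loc[self.table["chrom"] == chrom, "marker"].tolist()

    def chrom_of(self, marker: str):
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"unknown marker {marker!r}")
        return row["chrom"].iloc[0]

    def intervals(self, chrom) -> pd.DataFrame:
        """Adjacent-marker intervals on one chromosome (half-open in bp)."""
        sub = self.table.loc[self.table["chrom"] == chrom]
        left = sub.iloc[:-1].reset_index(drop=True)
        right = sub.iloc[1:].reset_index(drop=True)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "left": left["marker"],
                "right": right["marker"],
                "left_bp": left["pos"],
                "right_bp": right["pos"],
                "span_bp": right["pos"].to_numpy() - left["pos"].to_numpy(),
            }
        )

    def subset(self, marker_names) -> "MarkerMap":
        keep = self.table["marker"].isin(set(marker_names))
        return MarkerMap(self.table.loc[keep])

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.table.equals(other.table)


@dataclass(eq=False)
class GenotypeMatrix:
    """Backcross genotype calls, plants x markers.

    ``calls`` is an int8 DataFrame (rows = plant ids, columns = marker names in
    map order) with values :data:`CODE_A`, :data:`CODE_H` or
    :data:`CODE_MISSING`.
    """

    calls: pd.DataFrame
    marker_map: MarkerMap = field(repr=False)

    def __post_init__(self):
        expected = self.marker_map.marker_names
        got = list(self.calls.columns)
        if got != expected:
            raise ValueError(
                "genotype columns do not match marker map order "
                f"(first mismatch near {next((g for g, e in zip(got, expected) if g != e), '<length>')!r})"
            )
        vals = self.calls.to_numpy()
        bad = ~np.isin(vals, (CODE_A, CODE_H, CODE_MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {vals[i, j]!r} at plant "
                f"{self.calls.index[i]!r}, marker {self.calls.columns[j]!r}"
            )
        self.calls = self.calls.astype(np.int8)

    @property
    def n_plants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def codes(self, chrom) -> np.ndarray:
        """Plants x markers int8 code array for one chromosome."""
        return self.calls.loc[:, self.marker_map.markers(chrom)].to_numpy()

    def subset_markers(self, marker_names) -> "GenotypeMatrix":
        sub_map = self.marker_map.subset(marker_names)
        return GenotypeMatrix(self.calls.loc[:, sub_map.marker_names], sub_map)

    def subset_plants(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[np.asarray(mask)], self.marker_map)

    def missing_fraction_per_plant(self) -> pd.Series:
        return (self.calls == CODE_MISSING).mean(axis=1)

    def drop_high_missing_plants(self, max_missing_frac: float = 0.1) -> "GenotypeMatrix":
        keep = (self.missing_fraction_per_plant() <= max_missing_frac).to_numpy()
        return self.subset_plants(keep)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path, marker_map: MarkerMap) -> GenotypeMatrix:
    """Read a genotype TSV: header of marker names, one row per plant.

    The first column holds plant identifiers.  Calls must be ``A``, ``H`` or
    missing (``-``/``NA``); anything else is rejected with the offending cell
    named.  Marker columns must exactly match the map.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    unknown = [m for m in raw.columns if m not in set(marker_map.marker_names)]
    if unknown:
        raise ValueError(f"markers absent from the map: {unknown[:5]}")
    absent = [m for m in marker_map.marker_names if m not in set(raw.columns)]
    if absent:
        raise ValueError(f"map markers absent from the file: {absent[:5]}")
    raw = raw.loc[:, marker_map.marker_names]
    coded = np.empty(raw.shape, dtype=np.int8)
    vals = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            try:
                coded[i, j] = _CODE_OF_STR[vals[i, j]]
            except KeyError:
                raise ValueError(
                    f"invalid genotype code {vals[i, j]!r} at row "
                    f"{raw.index[i]!r}, column {raw.columns[j]!r}"
                ) from None
    calls = pd.DataFrame(coded, index=raw.index, columns=raw.columns)
    return GenotypeMatrix(calls, marker_map)


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    as_str = matrix.calls.replace(_STR_OF_CODE).astype(str)
    as_str.index.name = "plant"
    as_str.to_csv(path, sep="\t")


def flag_singletons(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Flag isolated discordant calls (genotyping-error signatures).

    A call is a singleton iff it differs from both its nearest non-missing
    neighbours on the same chromosome while those neighbours agree with each
    other.  Returns a DataFrame of (plant, chrom, marker) flags; the flag
    count is ``len(result)``.
    """
    records = []
    plants = matrix.calls.index
    for chrom in matrix.marker_map.chromosomes:
        names = matrix.marker_map.markers(chrom)
        codes = matrix.codes(chrom)
        for p in range(codes.shape[0]):
            row = codes[p]
            obs = np.flatnonzero(row != CODE_MISSING)
            if len(obs) < 3:
                continue
            vals = row[obs]
            mid = vals[1:-1]
            sandwich = (vals[:-2] == vals[2:]) & (mid != vals[:-2])
            for k in np.flatnonzero(sandwich):
                records.append((plants[p], chrom, names[obs[k + 1]]))
    return pd.DataFrame(records, columns=["plant", "chrom", "marker"])


# interval-table serialization: one row per adjacent-marker interval; numeric
# columns written with 6 significant digits, NaN as "NA"

def write_interval_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else format(v, ".6g")
            )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_interval_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def interval_table_roundtrip_equal(a: pd.DataFrame, b: pd.DataFrame, tol=1e-5) -> bool:
    """Equality up to the 6-significant-digit serialization."""
    if list(a.columns) != list(b.columns) or a.shape != b.shape:
        return False
    for col in a.columns:
        if pd.api.types.is_float_dtype(a[col]):
            x, y = a[col].to_numpy(), b[col].to_numpy()
            ok = np.isclose(x, y, rtol=tol, equal_nan=True)
            if not ok.all():
                return False
        elif not a[col].equals(b[col]):
            return False
    return True
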