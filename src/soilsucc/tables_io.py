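"""Tabular I/O and shared domain containers.

All tables travel as tab-delimited UTF-8 text.  Feature tables (OTUs or gene
families) are features-in-rows / samples-in-columns, the common convention for
microbiome count matrices; sample metadata is samples-in-rows.  Missing
covariates are empty cells and become NaN — downstream operations drop, never
impute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("soilsucc")

#: Ordered land-use stages of the abandonment gradient.
STAGES = ("managed", "recent", "late", "forest")
GRASSLAND_STAGES = ("managed", "recent", "late")

#: Fixed substrate panel of the catabolic (SIR) assay, simple to recalcitrant.
SIR_SUBSTRATES = ("glucose", "glycine", "oxalic_acid", "yeast", "lignin", "chitin")

FEATURE_KINDS = ("otu", "gene")
MARKERS = ("16S", "ITS", "metagenome", "predicted")


class TableFormatError(ValueError):
    """Malformed input table (duplicates, negative or non-numeric cells)."""


class AlignmentError(ValueError):
    """Two tables share no samples, or ids cannot be matched."""


class VocabularyError(ValueError):
    """A categorical column contains a label outside its closed vocabulary."""


@dataclass
class FeatureTable:
    """A feature-by-sample abundance matrix.

    ``values`` holds non-negative counts (or non-negative reals after
    normalization); rows are features, columns samples.
    """

    values: pd.DataFrame
    kind: str = "otu"
    marker: str = "16S"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise VocabularyError(f"unknown feature kind {self.kind!r}")
        if self.marker not in MARKERS:
            raise VocabularyError(f"unknown marker {self.marker!r}")
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate feature ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableFormatError("feature table contains non-numeric cells")
        if np.isnan(arr).any():
            raise TableFormatError("feature table contains missing cells")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative value at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)

    def with_values(self, values: pd.DataFrame) -> "FeatureTable":
        return replace(self, values=values)


def _as_stage_categorical(s: pd.Series) -> pd.Series:
    bad = set(s.dropna().unique()) - set(STAGES)
    if bad:
        raise VocabularyError(
            f"unknown stage label(s) {sorted(bad)}; expected one of {list(STAGES)}"
        )
    return pd.Series(
        pd.Categorical(s, categories=list(STAGES), ordered=True), index=s.index
    )


@dataclass
class SampleFrame:
    """Per-sample design and environmental covariates.

    ``data`` is indexed by sample_id.  ``stage`` is an ordered categorical over
    managed < recent < late < forest; ``ecosystem`` is derived (forest stage →
    forest, all grassland stages → grassland).  ``pair_id`` links each
    grassland sample to its adjacent forest reference; pairs missing one side
    are excluded from paired analyses with a warning.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise TableFormatError("duplicate sample ids in sample frame")
        if "stage" not in d.columns:
            raise TableFormatError("sample frame needs a 'stage' column")
        d = d.copy()
        d["stage"] = _as_stage_categorical(d["stage"])
        d["ecosystem"] = np.where(d["stage"] == "forest", "forest", "grassland")
        if "pair_distance_km" in d.columns:
            if (d["pair_distance_km"].dropna() < 0).any():
                raise TableFormatError("pair_distance_km must be >= 0")
        self.data = d

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def stage(self) -> pd.Series:
        return self.data["stage"]

    @property
    def ecosystem(self) -> pd.Series:
        return self.data["ecosystem"]

    def complete_pairs(self) -> pd.DataFrame:
        """Pairs with exactly one grassland and one forest sample.

        Returns a frame with columns pair_id, grassland, forest (sample ids).
        Broken pairs are dropped with a warning.
        """
        if "pair_id" not in self.data.columns:
            return pd.DataFrame(columns=["pair_id", "grassland", "forest"])
        rows, broken = [], []
        for pid, grp in self.data.dropna(subset=["pair_id"]).groupby(
            "pair_id", observed=True
        ):
            g = grp.index[grp["ecosystem"] == "grassland"]
            f = grp.index[grp["ecosystem"] == "forest"]
            if len(g) == 1 and len(f) == 1:
                rows.append((pid, g[0], f[0]))
            else:
                broken.append(pid)
        if broken:
            warnings.warn(
                f"pair(s) {broken} lack exactly one grassland and one forest "
                "sample; excluded from paired analyses",
                stacklevel=2,
            )
        return pd.DataFrame(rows, columns=["pair_id", "grassland", "forest"])

    def restrict(self, sample_ids) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)])


@dataclass
class TraitMatrix:
    """Taxa-by-gene-family copy-number matrix with family classifications.

    ``family_class`` maps every gene family to a nutrient cycle (C, N or P);
    ``substrate_class`` maps C-cycling families to the substrate category
    their enzymes act on (oligosaccharides through chitin/lignin).
    """

    values: pd.DataFrame
    family_class: dict[str, str] = field(default_factory=dict)
    substrate_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise TableFormatError("duplicate taxa or gene-family ids")
        if (v.to_numpy() < 0).any():
            raise TableFormatError("gene copy numbers must be >= 0")
        missing = [f for f in v.columns if f not in self.family_class]
        if self.family_class and missing:
            raise TableFormatError(f"gene families without nutrient class: {missing}")
        bad = set(self.family_class.values()) - {"C", "N", "P"}
        if bad:
            raise VocabularyError(f"unknown nutrient class(es): {sorted(bad)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def families(self) -> list[str]:
        return list(self.values.columns)

    def families_of_class(self, nutrient: str) -> list[str]:
        return [f for f in self.families if self.family_class.get(f) == nutrient]


@dataclass
class EffectSize:
    """A standardized effect with its confidence interval."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.estimate) or self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(path, kind: str = "otu", marker: str = "16S") -> FeatureTable:
    """Read a delimited feature-by-sample table.

    First column holds feature ids, header row sample ids.  Duplicated ids,
    negative values and non-numeric cells are rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(raw.columns):
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise TableFormatError(
                        f"non-numeric cell {cell!r} at row {raw.index[i]!r}, "
                        f"column {col!r}"
                    ) from None
        raise
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return FeatureTable(values=values, kind=kind, marker=marker)


def write_feature_table(ft: FeatureTable, path) -> None:
    ft.values.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_frame(path) -> SampleFrame:
    """Read sample metadata (samples in rows, first column sample_id)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    return SampleFrame(data)


def write_sample_frame(sf: SampleFrame, path) -> None:
    sf.data.to_csv(path, sep="\t", index_label="sample_id")


def read_trait_matrix(path, class_path=None) -> TraitMatrix:
    """Read a taxa-by-gene-family matrix, optionally with a family class map.

    ``class_path`` points to a TSV with columns gene_family, nutrient_class
    and (optionally) substrate_class.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    family_class: dict[str, str] = {}
    substrate_class: dict[str, str] = {}
    if class_path is not None:
        cls = pd.read_csv(class_path, sep="\t", index_col=0)
        family_class = cls["nutrient_class"].to_dict()
        if "substrate_class" in cls.columns:
            substrate_class = cls["substrate_class"].dropna().to_dict()
    return TraitMatrix(values=values, family_class=family_class,
                       substrate_class=substrate_class)


def write_trait_matrix(tm: TraitMatrix, path, class_path=None) -> None:
    tm.values.to_csv(path, sep="\t", index_label="taxon_id")
    if class_path is not None:
        cls = pd.DataFrame(
            {
                "nutrient_class": pd.Series(tm.family_class),
                "substrate_class": pd.Series(tm.substrate_class),
            }
        )
        cls.to_csv(class_path, sep="\t", index_label="gene_family")


def read_sir_table(path) -> pd.DataFrame:
    """Read per-sample respiration rates: sample_id, basal, six substrates."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in ("basal",) + SIR_SUBSTRATES if s not in df.columns]
    if missing:
        raise TableFormatError(f"SIR table missing column(s): {missing}")
    return df


def join_tables(ft: FeatureTable, sf: SampleFrame) -> tuple[FeatureTable, SampleFrame]:
    """Restrict a feature table and sample frame to their common samples.

    Both outputs carry the samples in the same order.  Idempotent; an empty
    intersection is an error.
    """
    common = [s for s in ft.sample_ids if s in set(sf.sample_ids)]
    if not common:
        raise AlignmentError("feature table and sample frame share no samples")
    dropped = (len(ft.sample_ids) - len(common)) + (len(sf.sample_ids) - len(common))
    if dropped:
        logger.info("join_tables: dropped %d unmatched sample(s)", dropped)
    return ft.with_values(ft.values[common]), sf.restrict(common)
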