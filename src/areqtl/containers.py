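"""In-memory containers shared across the pipeline.

Expression values are log2 intensities (probe-sets x samples); genotypes are
minor-allele dosages in {0, 1, 2} with NaN for missing calls.  Both wrap a
pandas DataFrame and carry light validation; everything heavier (per-SNP
metadata, detection flags) rides along as additional frames aligned by index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("NS", "SNC", "SC")  # never smokers / smokers no cancer / smokers with cancer


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ConfigError(ValueError):
    """Invalid configuration parameter."""


@dataclass
class ExpressionMatrix:
    """log2 expression, probe-sets in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame of finite log2 intensities.
    detection
        Optional boolean frame of the same shape: True where the probe was
        called detected (detection p <= 0.05) in that sample.
    """

    values: pd.DataFrame
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise InputError("duplicate probe ids")
        if v.columns.duplicated().any():
            raise InputError("duplicate sample ids")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise InputError("expression values must be finite")
        if self.detection is not None:
            d = self.detection
            if not (d.index.equals(v.index) and d.columns.equals(v.columns)):
                raise InputError("detection flags must align with values")
            self.detection = d.astype(bool)

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        det = None if self.detection is None else self.detection.loc[probe_ids]
        return ExpressionMatrix(self.values.loc[probe_ids], det)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        det = None if self.detection is None else self.detection[sample_ids]
        return ExpressionMatrix(self.values[sample_ids], det)


# Genotype dosage is float to allow NaN as missing.
SNP_META_COLUMNS = ("chrom", "pos", "ref", "alt", "snp_class")


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage per SNP x sample plus per-SNP metadata.

    ``meta`` is indexed by SNP id with columns chrom, pos (1-based), ref, alt
    and snp_class (free label such as ARE_SNP / tagSNP / sequenced).
    """

    dosage: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.dosage
        if d.index.duplicated().any():
            raise InputError("duplicate SNP ids")
        arr = d.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
        if not ok.all():
            raise InputError("dosage values must be 0/1/2 or missing")
        if not self.meta.index.equals(d.index):
            self.meta = self.meta.reindex(d.index)
        for col in ("chrom", "pos"):
            if col not in self.meta.columns:
                raise InputError(f"SNP metadata missing column {col!r}")
        if (pd.to_numeric(self.meta["pos"]) <= 0).any():
            raise InputError("SNP positions must be positive (1-based)")

    @property
    def snps(self) -> pd.Index:
        return self.dosage.index

    @property
    def samples(self) -> pd.Index:
        return self.dosage.columns


@dataclass
class GroundTruth:
    """What the simulator planted, for parameter-recovery checks.

    causal_pairs: (snp_id, gene_id, true beta in log2 units per allele)
    are_genes: gene ids carrying the SNC-up / SC-down group shifts
    planted_sites: (seq_id, start, end, strand) of embedded motif instances
    planted_snps: (seq_id, offset, ref, alt, inside_site)
    """

    causal_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    are_genes: list[str] = field(default_factory=list)
    planted_sites: list[tuple[str, int, int, str]] = field(default_factory=list)
    planted_snps: list[tuple[str, int, str, str, bool]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "causal_pairs": [list(t) for t in self.causal_pairs],
            "are_genes": list(self.are_genes),
            "planted_sites": [list(t) for t in self.planted_sites],
            "planted_snps": [list(t) for t in self.planted_snps],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            causal_pairs=[tuple(t) for t in d.get("causal_pairs", [])],
            are_genes=list(d.get("are_genes", [])),
            planted_sites=[tuple(t) for t in d.get("planted_sites", [])],
            planted_snps=[tuple(t) for t in d.get("planted_snps", [])],
        )


def check_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample annotation table (index = sample id).

    Requires a ``group`` column with values in NS/SNC/SC; age, pack_years and
    sex are used where present.
    """
    if samples.index.duplicated().any():
        raise InputError("duplicate sample ids in sample table")
    if "group" not in samples.columns:
        raise InputError("sample table needs a 'group' column")
    bad = set(samples["group"]) - set(GROUPS)
    if bad:
        raise InputError(f"unknown group labels: {sorted(bad)}")
    return samples
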