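"""In-memory containers and TSV round-trip for oGTT time-course metabolomics data.

The central object is :class:`TimeCourseDataset`: a sample x metabolite
intensity table plus sample metadata (subject, snack group, role, timepoint),
a metabolite annotation table (chemical class, structural fingerprint, KEGG
reactant-pair list), and a per-subject clinical table (Matsuda Index).

All on-disk formats are plain TSV so that a dataset directory is portable and
diffable; ground-truth objects from the simulator serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLE_STUDY = "study"
ROLE_QC = "qc"
ROLE_BLANK = "blank"

#: Snack-intervention arm labels, fixed across the package.
GROUPS = ("almond", "cracker")


@dataclasses.dataclass
class TimeCourseDataset:
    """Subjects x metabolites x timepoints intensity data with metadata.

    Parameters
    ----------
    samples
        One row per sample, indexed by ``sample_id``, with columns
        ``subject_id`` (empty for QC/blank rows), ``group``, ``role``
        (``study`` | ``qc`` | ``blank``) and ``timepoint_min``.
    intensities
        Non-negative intensity matrix indexed by ``sample_id`` with one
        column per metabolite; NaN marks a missing measurement.
    annotations
        Optional metabolite table indexed by metabolite id with columns
        ``chem_class``, ``fingerprint`` (hex-encoded bit string) and
        ``kegg_id``.
    clinical
        Optional per-subject table indexed by ``subject_id`` with a
        ``matsuda`` column (insulin-sensitivity index).
    kegg_pairs
        Optional two-column table (``metabolite_a``, ``metabolite_b``) of
        biochemical reactant-pair relationships.
    """

    samples: pd.DataFrame
    intensities: pd.DataFrame
    annotations: pd.DataFrame | None = None
    clinical: pd.DataFrame | None = None
    kegg_pairs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------

    @property
    def metabolites(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted study timepoints in minutes."""
        tp = self.samples.loc[self.samples["role"] == ROLE_STUDY, "timepoint_min"]
        return np.sort(tp.dropna().unique()).astype(float)

    def sample_ids(self, role: str) -> pd.Index:
        return self.samples.index[self.samples["role"] == role]

    def matrix(self, role: str = ROLE_STUDY) -> pd.DataFrame:
        """Intensity sub-matrix for samples of a given role."""
        return self.intensities.loc[self.sample_ids(role)]

    def study_meta(self) -> pd.DataFrame:
        return self.samples.loc[self.samples["role"] == ROLE_STUDY]

    def subjects(self) -> pd.DataFrame:
        """One row per study subject with its group label."""
        meta = self.study_meta()
        return (
            meta[["subject_id", "group"]]
            .drop_duplicates()
            .set_index("subject_id")
            .sort_index()
        )

    # -- manipulation ----------------------------------------------------

    def restrict(self, metabolites: Iterable[str]) -> "TimeCourseDataset":
        """A copy keeping only the given metabolites (order preserved)."""
        keep = [m for m in self.metabolites if m in set(metabolites)]
        ann = self.annotations.loc[self.annotations.index.isin(keep)] if self.annotations is not None else None
        kp = None
        if self.kegg_pairs is not None:
            ks = set(keep)
            kp = self.kegg_pairs[
                self.kegg_pairs["metabolite_a"].isin(ks)
                & self.kegg_pairs["metabolite_b"].isin(ks)
            ].reset_index(drop=True)
        return TimeCourseDataset(
            samples=self.samples.copy(),
            intensities=self.intensities[keep].copy(),
            annotations=ann.copy() if ann is not None else None,
            clinical=self.clinical.copy() if self.clinical is not None else None,
            kegg_pairs=kp,
        )

    def study_array(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Pivot study intensities into a (subject, timepoint, metabolite) cube.

        Returns ``(subject_ids, timepoints, cube)`` where absent samples are
        NaN planes. Subjects are sorted; timepoints ascend.
        """
        meta = self.study_meta()
        subs = sorted(meta["subject_id"].unique())
        tps = self.timepoints
        cube = np.full((len(subs), len(tps), len(self.metabolites)), np.nan)
        s_idx = {s: i for i, s in enumerate(subs)}
        t_idx = {t: i for i, t in enumerate(tps)}
        vals = self.intensities.loc[meta.index].to_numpy()
        for row, (sid, tp) in enumerate(zip(meta["subject_id"], meta["timepoint_min"])):
            cube[s_idx[sid], t_idx[float(tp)]] = vals[row]
        return subs, tps, cube

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if not self.samples.index.equals(self.intensities.index):
            raise ValueError("samples and intensities must share the same sample_id index")
        if self.intensities.columns.duplicated().any():
            dup = self.intensities.columns[self.intensities.columns.duplicated()][0]
            raise ValueError(f"duplicate metabolite identifier: {dup!r}")
        study = self.study_meta()
        if study["subject_id"].isna().any() or study["group"].isna().any():
            raise ValueError("every study sample needs a subject_id and group")
        if study["timepoint_min"].isna().any():
            raise ValueError("every study sample needs a timepoint_min")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy() < 0).any():
                raise ValueError("intensities must be non-negative")

    # -- persistence -----------------------------------------------------

    def to_dir(self, path: str | Path) -> Path:
        """Write the dataset as a directory of TSV tables."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(path / "samples.tsv", sep="\t", index_label="sample_id")
        self.intensities.to_csv(path / "intensities.tsv", sep="\t", index_label="sample_id")
        if self.annotations is not None:
            self.annotations.to_csv(path / "annotations.tsv", sep="\t", index_label="metabolite")
        if self.clinical is not None:
            self.clinical.to_csv(path / "clinical.tsv", sep="\t", index_label="subject_id")
        if self.kegg_pairs is not None:
            self.kegg_pairs.to_csv(path / "kegg_pairs.tsv", sep="\t", index=False)
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "TimeCourseDataset":
        path = Path(path)
        samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col="sample_id")
        intensities = pd.read_csv(path / "intensities.tsv", sep="\t", index_col="sample_id")
        annotations = clinical = kegg_pairs = None
        if (path / "annotations.tsv").exists():
            annotations = pd.read_csv(path / "annotations.tsv", sep="\t", index_col="metabolite")
        if (path / "clinical.tsv").exists():
            clinical = pd.read_csv(path / "clinical.tsv", sep="\t", index_col="subject_id")
        if (path / "kegg_pairs.tsv").exists():
            kegg_pairs = pd.read_csv(path / "kegg_pairs.tsv", sep="\t")
        return cls(samples, intensities, annotations, clinical, kegg_pairs)


@dataclasses.dataclass
class GroundTruth:
    """Machine-readable record of everything the simulator planted.

    ``affected`` maps metabolite id to the signed standardized effect planted
    on its full-window log-AUC; ``archetype_of`` covers every non-artifact
    metabolite; ``planted_correlations`` holds (metabolite, group, r) triples
    realized exactly in the generated sample.
    """

    affected: dict[str, float]
    archetype_of: dict[str, str]
    enriched_class: str | None
    enriched_members: list[str]
    biphasic_class: str | None
    biphasic_members: list[str]
    planted_correlations: list[tuple[str, str, float]]
    blank_artifacts: list[str]
    high_rsd_metabolites: list[str]
    mi_metabolite: str | None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["planted_correlations"] = [tuple(t) for t in raw["planted_correlations"]]
        return cls(**raw)


def fingerprint_from_hex(hex_string: str, n_bits: int = 64) -> np.ndarray:
    """Decode a hex-encoded structural fingerprint into a boolean bit vector."""
    value = int(hex_string, 16)
    bits = np.array([(value >> i) & 1 for i in range(n_bits)], dtype=bool)
    return bits[::-1]


def fingerprint_to_hex(bits: Sequence[bool] | np.ndarray) -> str:
    bits = np.asarray(bits, dtype=bool)
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return format(value, f"0{int(np.ceil(len(bits) / 4))}x")
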