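"""Standard-format I/O: imzML, FASTA, CSV tables, YAML configuration.

All tabular writers emit a stable column order and fixed float formatting
so that a rerun with identical inputs reproduces byte-identical files.
Feature-matrix headers format m/z to 4 decimals; data columns keep full
precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .containers import META_COLUMNS, FeatureMatrix, MSIDataset, Spectrum

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# imzML

def write_imzml(dataset: MSIDataset, path) -> None:
    """Write a continuous-mode imzML/ibd pair.

    Pixel coordinates come from the metadata; ROI annotations are not part
    of imzML and are written separately (see :func:`write_roi_table`).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous") as writer:
        for i in range(dataset.n_spectra):
            row = dataset.meta.iloc[i]
            writer.addSpectrum(
                dataset.mz_axis,
                np.asarray(dataset.intensities[i], dtype=float),
                coords=(int(row["x"]), int(row["y"])),
            )


def read_imzml(path) -> tuple[list[Spectrum], str]:
    """Read an imzML file into per-pixel spectra.

    Works for continuous and processed mode; returns the spectra (m/z
    ascending enforced) and the recorded mode string.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    # in continuous mode every spectrum references one shared m/z array
    mode = "continuous" if len(set(parser.mzOffsets)) == 1 else "processed"
    spectra = []
    for i, coords in enumerate(parser.coordinates):
        mz, intens = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        intens = np.asarray(intens, dtype=float)
        order = np.argsort(mz, kind="stable")
        spectra.append(
            Spectrum(mz=mz[order], intensities=np.maximum(intens[order], 0.0),
                     x=int(coords[0]), y=int(coords[1]))
        )
    return spectra, mode


def read_msi(imzml_path, roi_table_path) -> MSIDataset:
    """Read a continuous-mode imzML plus its ROI annotation table into one
    dataset; annotation rows are joined on spectrum index."""
    spectra, mode = read_imzml(imzml_path)
    if mode != "continuous":
        raise ValueError("read_msi requires a continuous-mode imzML file")
    meta = read_roi_table(roi_table_path)
    if len(meta) != len(spectra):
        raise ValueError(
            f"ROI table has {len(meta)} rows but imzML has {len(spectra)} spectra"
        )
    ds = MSIDataset.from_spectra(spectra)
    ds.meta = meta.reset_index(drop=True)
    return ds


# ---------------------------------------------------------------------------
# CSV tables

def write_roi_table(meta: pd.DataFrame, path) -> None:
    meta.loc[:, list(META_COLUMNS)].to_csv(path, index=False)


def read_roi_table(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"patient_id": str, "roi_id": str,
                                    "roi_class": str})
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"ROI table missing column(s): {sorted(missing)}")
    return meta.loc[:, list(META_COLUMNS)]


def write_feature_matrix(matrix: FeatureMatrix, path, meta_path=None) -> None:
    """Feature matrix as CSV: one row per spectrum, features as columns
    labelled by their m/z to 4 decimals, plus a sidecar metadata CSV."""
    df = pd.DataFrame(
        np.asarray(matrix.intensities, dtype=float),
        columns=[f"{m:.4f}" for m in matrix.feature_mz],
    )
    df.insert(0, "spectrum_index", matrix.meta["spectrum_index"].to_numpy())
    with open(path, "w") as fh:
        fh.write("# feature_mz_full_precision: "
                 + ",".join(FLOAT_FORMAT % m for m in matrix.feature_mz) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
    if meta_path is not None:
        write_roi_table(matrix.meta, meta_path)


def read_feature_matrix(path, meta_path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# feature_mz_full_precision:"):
            raise ValueError("not a feature-matrix CSV (missing m/z header)")
        feature_mz = np.array(
            [float(x) for x in header.split(":", 1)[1].split(",") if x.strip()]
        )
        df = pd.read_csv(fh)
    meta = read_roi_table(meta_path)
    intens = df.drop(columns=["spectrum_index"]).to_numpy()
    return FeatureMatrix(feature_mz=feature_mz, intensities=intens, meta=meta)


def write_table(df: pd.DataFrame, path) -> None:
    """Generic stable CSV writer used for screen/match/enrichment tables."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(proteins: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# YAML config helpers

def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
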