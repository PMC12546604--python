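"""End-to-end synthetic experiment generation: design -> phenotypes -> images."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .embeddings import embed_compound
from .render import RenderParams, render_image
from .scm import (
    CompoundRecord,
    ExperimentDesign,
    ObservationRecord,
    ScmParams,
    confounder_code,
    render_params_for,
    sample_phenotype,
)
from .utils import as_rng


def generate_dataset(
    design: ExperimentDesign,
    params: ScmParams,
    compounds: list[CompoundRecord],
    render_params: RenderParams | None = None,
    rng: int | np.random.Generator = 0,
    out_dir: str | os.PathLike | None = None,
    embedding_dim: int | None = None,
) -> tuple[list[ObservationRecord], pd.DataFrame]:
    """Simulate one full experiment.

    Produces one :class:`ObservationRecord` per (plate, well, fov) and a
    ground-truth table carrying treatment, confounder metadata, labels and
    the hidden phenotype (``GT_P_*`` columns). Phenotypes are sampled once
    per well (cells in a well share biology); each FoV is an independent
    render of that phenotype. When ``out_dir`` is given, images are written
    as multi-page TIFFs and the table as ``metadata.parquet``.
    """
    rng = as_rng(rng)
    rp = render_params or RenderParams()
    dim = embedding_dim or params.embedding_dim
    by_id = {c.compound_id: c for c in compounds}
    embeddings = {
        c.compound_id: embed_compound(c.smiles, dim) for c in compounds
    }

    records: list[ObservationRecord] = []
    rows = []
    well_phenotype: dict[tuple[str, int, int], np.ndarray] = {}
    for assignment, compound_id in design.iter_assignments():
        if compound_id not in by_id:
            raise KeyError(f"design allocates unknown compound {compound_id!r}")
        code = confounder_code(assignment, design)
        wkey = (assignment.plate_id, assignment.well_row, assignment.well_col)
        if wkey not in well_phenotype:
            well_phenotype[wkey] = sample_phenotype(
                embeddings[compound_id], code, params, rng
            )
        phenotype = well_phenotype[wkey]
        image = render_image(
            phenotype,
            render_params=rp,
            rng=rng,
            observation_effect=render_params_for(code, params),
        )
        records.append(ObservationRecord(image, compound_id, assignment, phenotype))
        rec = by_id[compound_id]
        row = {
            "Metadata_Source": assignment.source_id,
            "Metadata_Batch": assignment.batch_id,
            "Metadata_Plate": assignment.plate_id,
            "Metadata_Well": assignment.well_name,
            "Metadata_FoV": assignment.fov_index,
            "Metadata_Compound": compound_id,
            "Metadata_SMILES": rec.smiles,
            "Metadata_MoA": rec.moa_label or "",
            "Metadata_Targets": ";".join(sorted(rec.target_labels)),
        }
        for j, v in enumerate(phenotype):
            row[f"GT_P_{j}"] = v
        rows.append(row)

    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        filenames = []
        for rec, row in zip(records, rows):
            fname = io.image_filename(
                row["Metadata_Source"], row["Metadata_Batch"], row["Metadata_Plate"],
                row["Metadata_Well"], row["Metadata_FoV"],
            )
            io.write_image_stack(rec.image, out_dir / fname)
            filenames.append(fname)
        table = table.assign(Metadata_File=filenames)
        io.write_profiles(table, out_dir / "metadata.parquet")
    return records, table
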