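"""High-level orchestration: records -> annotations -> feature table.

This is the layer the CLI and end-to-end workflows sit on; each function is
stateless and record-order independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AntibodyAnnotation, ScFvRecord, annotate_scfv
from .embeddings import EmbeddingSpec, concat_features, embed
from .errors import PolyScfvError
from .hydro import HydroConstants, hydrodynamic_panel, read_pdb
from .seqfeat import FeatureVector, assemble_f46, f46_registry, registry_manifest


@dataclass
class FeaturizeResult:
    table: pd.DataFrame          # one row per record, columns = registry
    labels: pd.Series            # aligned labels (NaN when unlabelled)
    incomplete_ids: list[str]    # records lacking structure features
    failed: dict[str, str] = field(default_factory=dict)  # id -> error

    @property
    def X(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=float).astype(int)


def _hydro_for(record: ScFvRecord, constants: HydroConstants):
    if record.structure is not None:
        return hydrodynamic_panel(record.structure, constants).to_dict()
    if record.structure_path is not None:
        model = read_pdb(record.structure_path)
        return hydrodynamic_panel(model, constants).to_dict()
    return None


def featurize_records(
    records: list[ScFvRecord],
    embedding_spec: EmbeddingSpec | None = None,
    constants: HydroConstants = HydroConstants(),
    skip_bad: bool = False,
    annotations: Mapping[str, AntibodyAnnotation] | None = None,
) -> FeaturizeResult:
    """Annotate and featurize records into an id-indexed feature table.

    With ``embedding_spec`` set, the embedding block is appended after the
    biochemical panel.  A record that fails annotation raises unless
    ``skip_bad``, in which case it is recorded in ``failed``.
    """
    rows: list[FeatureVector] = []
    ids: list[str] = []
    labels: list[float] = []
    incomplete: list[str] = []
    failed: dict[str, str] = {}
    for rec in records:
        try:
            ann = (
                annotations[rec.id]
                if annotations is not None and rec.id in annotations
                else annotate_scfv(rec)
            )
            fv = assemble_f46(rec, ann, _hydro_for(rec, constants))
            if embedding_spec is not None:
                vec = embed(rec.sequence, embedding_spec)
                fv = concat_features(fv, vec, embedding_spec.name)
        except PolyScfvError as exc:
            if not skip_bad:
                raise
            failed[rec.id] = str(exc)
            continue
        if not fv.complete:
            incomplete.append(rec.id)
        rows.append(fv)
        ids.append(rec.id)
        labels.append(np.nan if rec.label is None else float(rec.label))
    if rows:
        table = pd.DataFrame(
            np.stack([fv.values for fv in rows]),
            index=pd.Index(ids, name="id"),
            columns=rows[0].names,
        )
    else:
        table = pd.DataFrame(columns=f46_registry())
    return FeaturizeResult(
        table=table,
        labels=pd.Series(labels, index=table.index, name="label"),
        incomplete_ids=incomplete,
        failed=failed,
    )


def config_hash(config: Mapping[str, object]) -> str:
    """Stable short hash of a resolved run configuration."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def feature_manifest(
    embedding_spec: EmbeddingSpec | None = None,
) -> dict[str, object]:
    manifest = registry_manifest()
    if embedding_spec is not None:
        manifest["embedding"] = {
            "provider": embedding_spec.name,
            "dim": embedding_spec.dim,
            "pooling": embedding_spec.pooling,
        }
    return manifest
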