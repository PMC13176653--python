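"""End-to-end workflows chaining the pipeline stages.

Two workflows mirror how the methods are used together: *discovery* turns
translated-search hits into complete candidate ORFs, featurises them and
scores them with the trained classifier; *locus analysis* runs the
degree-centrality locus detection over multi-species annotations and
assigns every IFN gene to a conserved locus or the exception category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneRecord
from .apaac import ApaacParams, featurize
from .orf_scanner import (
    CandidateORF,
    HomologyHit,
    extend_to_orf,
    screen_candidates,
)
from .scope_classifier import LabeledDataset, ScopeModel, predict, train_scope
from .synthetic_data import Pangenome, build_training_set, emit_hits


def run_discovery(
    hits: Sequence[HomologyHit],
    genome: Mapping[str, str],
    annotated: Sequence[GeneRecord],
    model: ScopeModel,
    species: str,
    params: ApaacParams | None = None,
    max_extension: int = 6000,
) -> pd.DataFrame:
    """Hits → ORFs → features → predictions for one species.

    Returns a candidate table ranked by predicted probability; candidates
    overlapping annotated IFNs are screened out beforehand.  An empty hit
    list yields an empty table.
    """
    params = params or ApaacParams()
    orfs: list[CandidateORF] = []
    for hit in hits:
        orf = extend_to_orf(hit, genome, max_extension=max_extension)
        if orf is not None:
            orfs.append(orf)
    survivors = screen_candidates(orfs, annotated, species)
    columns = [
        "name", "chromosome", "start", "end", "strand",
        "probability", "predicted_ifn", "protein",
    ]
    if not survivors:
        return pd.DataFrame(columns=columns)
    features = featurize(
        {o.name: o.protein for o in survivors}, params, skip_invalid=True
    )
    labels, probs = predict(model, features.to_numpy())
    by_name = {o.name: o for o in survivors}
    rows = []
    for name, label, prob in zip(features.index, labels, probs):
        orf = by_name[name]
        rows.append(
            {
                "name": name,
                "chromosome": orf.chromosome,
                "start": orf.start,
                "end": orf.end,
                "strand": orf.strand,
                "probability": float(prob),
                "predicted_ifn": bool(label),
                "protein": orf.protein,
            }
        )
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values("probability", ascending=False, ignore_index=True)


@dataclass
class DiscoveryOutcome:
    """Bookkeeping of a full synthetic discovery round."""

    model: ScopeModel
    candidates: pd.DataFrame
    n_planted_unannotated: int
    n_recovered: int
    false_positive_rate: float

    @property
    def recovery_rate(self) -> float:
        if self.n_planted_unannotated == 0:
            return float("nan")
        return self.n_recovered / self.n_planted_unannotated


def discover_in_pangenome(
    pangenome: Pangenome,
    params: ApaacParams | None = None,
    seed: int = 0,
    jitter: int = 30,
    holdout_negatives: int = 300,
) -> DiscoveryOutcome:
    """Simulate-to-prediction round trip on one pangenome.

    Trains the classifier on the pangenome's annotated genes, emits
    pseudo-hits for every genomic IFN ORF, extends and screens them, and
    scores the surviving (unannotated) candidates.  Recovery counts
    planted unannotated IFNs whose exact interval was predicted positive;
    the false-positive rate is measured on held-out neighbour proteins
    never seen in training.
    """
    params = params or ApaacParams()
    dataset = build_training_set(pangenome, params, seed=seed)
    model = train_scope(dataset, seed=seed)

    hits = emit_hits(pangenome, jitter=jitter, seed=seed)
    frames = []
    for species in pangenome.species:
        sub = hits[hits["species"] == species]
        species_hits = [
            HomologyHit(
                query_id=str(r.qseqid),
                subject_chromosome=str(r.sseqid),
                subject_start=int(min(r.sstart, r.send)),
                subject_end=int(max(r.sstart, r.send)),
                strand="+" if r.sstart <= r.send else "-",
                evalue=float(r.evalue),
            )
            for r in sub.itertuples(index=False)
        ]
        frame = run_discovery(
            species_hits,
            pangenome.sequences[species],
            pangenome.records[species],
            model,
            species,
            params=params,
        )
        frame.insert(0, "species", species)
        if len(frame):
            frames.append(frame)
    candidates = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "species", "name", "chromosome", "start", "end", "strand",
                "probability", "predicted_ifn", "protein",
            ]
        )
    )

    planted = pangenome.truth[
        pangenome.truth["is_ifn1"] & ~pangenome.truth["annotated"]
    ]
    positive = candidates[candidates["predicted_ifn"]] if len(candidates) else candidates
    predicted_keys = (
        {
            (r.species, r.chromosome, r.start, r.end)
            for r in positive.itertuples(index=False)
        }
        if len(positive)
        else set()
    )
    recovered = sum(
        (r.species, r.chromosome, r.start, r.end) in predicted_keys
        for r in planted.itertuples(index=False)
    )

    # held-out neighbour proteins (never in the training subsample)
    rng = np.random.default_rng([pangenome.config.seed, 888, seed])
    training_ids = set(dataset.ids)
    pool = [
        r.id
        for r in pangenome.truth.itertuples(index=False)
        if r.annotated and not r.is_ifn1 and r.id not in training_ids
    ]
    fp_rate = float("nan")
    if pool:
        take = min(holdout_negatives, len(pool))
        chosen = [pool[i] for i in rng.choice(len(pool), size=take, replace=False)]
        feats = featurize({i: pangenome.proteins[i] for i in chosen}, params)
        labels, _ = predict(model, feats.to_numpy())
        fp_rate = float(np.mean(labels))

    return DiscoveryOutcome(
        model=model,
        candidates=candidates,
        n_planted_unannotated=len(planted),
        n_recovered=int(recovered),
        false_positive_rate=fp_rate,
    )
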