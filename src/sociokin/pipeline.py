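"""End-to-end orchestration: fixes + genotypes -> association network,
social units, relatedness/diversity, spatial overlap, and matrix tests.

Every run is driven by a :class:`~sociokin.config.PipelineConfig`; the
seed is recorded in every JSON summary and identical (config, seed,
inputs) runs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, genetics, matrix_stats, network, spatial
from .config import PipelineConfig
from .genetics import GenotypeTable
from .io import write_matrix

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable({k: v for k, v in dataclasses.asdict(obj).items()
                          if k != "null_samples"})
    return obj


def run_pipeline(
    fixes: pd.DataFrame,
    genotypes: GenotypeTable | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full socio-genetic network analysis.

    Returns a dict of result objects; when ``outdir`` is given, writes
    hwi.csv, units.csv, relatedness.csv, overlap.csv, associations.csv
    and a summary.json mirroring the returned summaries.
    """
    config = config or PipelineConfig()
    results: dict = {"config": config.to_dict()}

    records = associations.detect_associations(fixes, config)
    hwi = associations.hwi_matrix(records)
    results["records"] = records
    results["hwi"] = hwi
    results["hwi_summary"] = associations.association_summary(hwi)
    results["permutation"] = associations.permutation_test(
        records,
        n_perm=config.n_permutations_association,
        seed=config.random_seed,
    )

    part = network.best_partition(hwi)
    results["partition"] = part
    results["unit_stats"] = network.unit_stats(part, mark_rate=config.mark_rate)

    overlap = spatial.overlap_matrix(fixes, config)
    results["overlap"] = overlap
    results["mantel_overlap_hwi"] = matrix_stats.mantel(
        overlap, hwi, n_perm=config.n_permutations_matrix,
        seed=config.random_seed,
    )

    if genotypes is not None:
        rel = genetics.qg_relatedness(genotypes)
        results["relatedness"] = rel
        results["diversity"] = genetics.diversity_stats(genotypes)
        results["mantel_hwi_relatedness"] = matrix_stats.mantel(
            hwi, rel, n_perm=config.n_permutations_matrix,
            seed=config.random_seed,
        )
        results["partial_mantel_hwi_relatedness_overlap"] = matrix_stats.partial_mantel(
            hwi, rel, overlap, n_perm=config.n_permutations_matrix,
            seed=config.random_seed,
        )
        results["within_between_relatedness"] = matrix_stats.within_between_test(
            rel, part, n_perm=config.n_permutations_matrix,
            seed=config.random_seed,
        )
        results["within_between_overlap"] = matrix_stats.within_between_test(
            overlap, part, n_perm=config.n_permutations_matrix,
            seed=config.random_seed,
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(hwi, outdir / "hwi.csv")
        write_matrix(overlap, outdir / "overlap.csv")
        if genotypes is not None:
            write_matrix(results["relatedness"], outdir / "relatedness.csv")
            results["diversity"].to_csv(outdir / "diversity.csv")
        pd.DataFrame(
            [(r.day, a, b) for r in records for a, b in sorted(r.dyads)],
            columns=["day", "id_a", "id_b"],
        ).to_csv(outdir / "associations.csv", index=False)
        pd.DataFrame(
            {"id": part.ids, "unit": part.labels}
        ).to_csv(outdir / "units.csv", index=False)
        summary = {
            k: _jsonable(v) for k, v in results.items()
            if k not in ("records", "hwi", "overlap", "relatedness", "diversity")
            and not isinstance(v, network.Partition)
        }
        summary["partition"] = {
            "q": part.q, "n_units": part.n_units, "sizes": part.sizes(),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("pipeline outputs written to %s", outdir)
    return results
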