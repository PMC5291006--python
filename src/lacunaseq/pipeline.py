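"""Per-subject analysis pipeline and batch driver.

One subject's analysis chains the stages: apply calls to the reference,
build the weighted CGR matrix, min-max normalize, sigmoid-preprocess,
compute the gliding-box lacunarity curve, and fit the hyperbola model.  The
default configuration is the operating point that gave stable cohort
separation: L=5, b_min=3, k=7, sigma=0.7.

No stage uses unseeded randomness, so repeated runs of the same subject are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import cgr as _cgr
from . import hypfit as _hypfit
from . import lacunarity as _lac
from .cohort import SubjectResult
from .seqio import CallTable, NucleotideSequence, apply_calls, read_call_table, read_fasta

logger = logging.getLogger("lacunaseq")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the per-subject pipeline."""

    frame_length: int = 5      # CGR frame length L
    b_min: int = 3             # smallest gliding-box size (pixels)
    b_max: int | None = None   # None = "auto": half the image side
    k: float = 7.0             # sigmoid steepness
    sigma: float = 0.7         # sigmoid gray-level midpoint
    circular: bool = False     # wrap-around CGR windows

    def __post_init__(self) -> None:
        if not 1 <= self.frame_length <= _cgr.MAX_FRAME_LENGTH:
            raise ValueError(f"frame_length must be in [1, {_cgr.MAX_FRAME_LENGTH}]")
        if self.b_min < 2:
            raise ValueError("b_min must be >= 2")
        if self.k <= 0 or self.sigma <= 0:
            raise ValueError("k and sigma must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a JSON config file; keyword overrides win over file values."""
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha1(text: str) -> str:
    return hashlib.sha1(text.encode()).hexdigest()


def analyze_subject(
    reference: NucleotideSequence,
    calls: CallTable,
    config: PipelineConfig = PipelineConfig(),
    *,
    subject_id: str = "subject",
    group: str = "",
    out_dir: str | Path | None = None,
    keep_intermediates: bool = False,
) -> SubjectResult:
    """Run the full per-subject pipeline and return the fitted result.

    When ``out_dir`` is given, the fit JSON, the mutation report and run
    metadata are written there; ``keep_intermediates`` additionally writes
    the CGR matrix and the lacunarity curve.
    """
    logger.info("[%s] applying %d calls to %s", subject_id, len(calls), reference.name)
    mutated = apply_calls(reference, calls)

    logger.info("[%s] CGR at L=%d", subject_id, config.frame_length)
    matrix = _cgr.cgr_matrix(mutated, config.frame_length, circular=config.circular)
    report = _cgr.mutation_report(reference, calls, mutated)

    img = _lac.normalize_matrix(matrix.values)
    img = _lac.sigmoid_preprocess(img, _lac.SigmoidParams(k=config.k, sigma=config.sigma))

    logger.info("[%s] gliding-box lacunarity, b_min=%d", subject_id, config.b_min)
    curve = _lac.lacunarity_curve(img, config.b_min, config.b_max)
    fit = _hypfit.fit_hyperbola(curve)
    logger.info(
        "[%s] fit: alpha=%.4f beta=%.4f gamma=%.4f (converged=%s)",
        subject_id, fit.alpha, fit.beta, fit.gamma, fit.converged,
    )

    result = SubjectResult(
        subject_id=subject_id,
        group=group,
        beta=fit.beta,
        alpha=fit.alpha,
        gamma=fit.gamma,
        n_mutations_homo=report.n_homoplasmic,
        n_mutations_hetero=report.n_heteroplasmic,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _hypfit.write_fit_json(fit, out_dir / f"{subject_id}.json")
        _cgr.write_report_json(report, out_dir / f"{subject_id}.report.json")
        with open(out_dir / f"{subject_id}.run.json", "w") as fh:
            json.dump(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "config": config.to_dict(),
                    "reference_sha1": _sha1(reference.symbols),
                    "sequence_sha1": _sha1(mutated.symbols),
                    "n_calls": len(calls),
                },
                fh,
                indent=2,
            )
        if keep_intermediates:
            _cgr.write_matrix_csv(matrix, out_dir / f"{subject_id}.cgr.csv")
            _cgr.write_pgm(matrix.values, out_dir / f"{subject_id}.cgr.pgm")
            _lac.write_curve_csv(curve, out_dir / f"{subject_id}.curve.csv")
    return result


def run_batch(
    reference_path: str | Path,
    manifest_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path = "results",
    keep_intermediates: bool = False,
) -> list[SubjectResult]:
    """Process every subject in a manifest TSV (subject_id, calls, group).

    Call-table paths in the manifest are resolved relative to the manifest's
    own directory.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    reference = read_fasta(reference_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "calls", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    results = []
    for _, row in df.iterrows():
        calls_path = Path(row["calls"])
        if not calls_path.is_absolute():
            calls_path = manifest_path.parent / calls_path
        calls = read_call_table(calls_path)
        results.append(
            analyze_subject(
                reference,
                calls,
                config,
                subject_id=row["subject_id"],
                group=row["group"],
                out_dir=out_dir,
                keep_intermediates=keep_intermediates,
            )
        )
    return results
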