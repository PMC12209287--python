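"""Record-to-feature pipeline shared by the model, the CLI and tests.

Order of computation per record: semantic flags -> min-max-scaled age
and requested duration -> Burden_Score -> fuzzy inference
(Expanded_Score) -> ten-feature classifier vector.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_BURDEN_WEIGHTS,
    FEATURE_NAMES,
    BurdenWeights,
    apply_minmax,
    build_feature_vector,
    burden_score,
    fit_minmax,
)
from .fuzzy import FuzzyConfig, FuzzyInput, InferenceResult, infer
from .lexicon import Lexicon, extract_flags
from .records import JudgmentRecord

#: Scaler params used when tracing a single case without a fitted model:
#: a plausible adult age span and the half-year-to-five-year request grid.
DEFAULT_TRACE_SCALERS: dict[str, tuple[float, float]] = {
    "age": (18.0, 90.0),
    "time_requested": (0.5, 5.0),
}


def fit_scalers(records: Sequence[JudgmentRecord]) -> dict[str, tuple[float, float]]:
    """Fit the fuzzy layer's min-max scalers (age, requested duration)
    on a training split."""
    return {
        "age": fit_minmax([r.age_years for r in records]),
        "time_requested": fit_minmax([r.time_requested_years for r in records]),
    }


def analyse_record(
    record: JudgmentRecord,
    lexicon: Lexicon | None = None,
    fuzzy_config: FuzzyConfig | None = None,
    scalers: Mapping[str, tuple[float, float]] | None = None,
    weights: BurdenWeights = DEFAULT_BURDEN_WEIGHTS,
) -> dict:
    """Run the full per-case pipeline; returns flags, burden, fuzzy
    result and the feature vector in one dict (the CLI ``trace``
    command prints exactly this)."""
    lexicon = lexicon or Lexicon()
    scalers = scalers or DEFAULT_TRACE_SCALERS
    flags = extract_flags(record.main_diagnosis, record.other_diagnoses,
                          record.symptoms_text, lexicon)
    age_norm = apply_minmax(record.age_years, scalers["age"])
    treq_norm = apply_minmax(record.time_requested_years,
                             scalers["time_requested"])
    burden = burden_score(flags.severity_flag, flags.compliance_flag,
                          treq_norm, int(record.substance_use_reported),
                          weights)
    fin = FuzzyInput(
        age_norm=age_norm,
        time_requested_norm=treq_norm,
        severity=flags.severity_flag,
        noncompliance=flags.compliance_flag,
        substance_use=int(record.substance_use_reported),
        sex=record.sex,
        legal_aid=int(record.legal_aid),
        burden_score=burden,
    )
    result: InferenceResult = infer(fin, fuzzy_config)
    vector = build_feature_vector(record, flags, burden, result.score)
    return {
        "flags": flags,
        "age_norm": age_norm,
        "time_requested_norm": treq_norm,
        "burden_score": burden,
        "fuzzy_input": fin,
        "fuzzy": result,
        "features": vector,
    }


def featurize(
    records: Sequence[JudgmentRecord],
    lexicon: Lexicon | None = None,
    fuzzy_config: FuzzyConfig | None = None,
    scalers: Mapping[str, tuple[float, float]] | None = None,
    weights: BurdenWeights = DEFAULT_BURDEN_WEIGHTS,
) -> pd.DataFrame:
    """Feature matrix (columns = :data:`FEATURE_NAMES` plus
    ``fuzzy_category``) for a list of records."""
    rows = []
    cats = []
    for rec in records:
        info = analyse_record(rec, lexicon, fuzzy_config, scalers, weights)
        rows.append(info["features"])
        cats.append(info["fuzzy"].category)
    df = pd.DataFrame(np.vstack(rows) if rows else
                      np.empty((0, len(FEATURE_NAMES))),
                      columns=list(FEATURE_NAMES))
    df["fuzzy_category"] = cats
    return df


def outcome_labels(records: Sequence[JudgmentRecord]) -> np.ndarray:
    """Binary outcome vector: 1 = entire acceptance, 0 = partial."""
    return np.array([1 if r.acceptance_extent == "entire" else 0
                     for r in records], dtype=int)
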