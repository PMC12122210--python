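"""Published clinical-scale concordance counts used as reference inputs.

The original clinical-scale study of homologous-variant concordance
(ClinVar/gnomAD variants over curated family seed alignments) reported
pair counts per category mode and identity stratum, together with
two-decimal sensitivity/specificity/accuracy/MCC.  The class counts are
inputs here: recomputing the metrics from them exercises the directional
confusion expansion and the metric formulas against independently
published values.
"""

from __future__ import annotations

from .metrics import ConfusionCounts, MetricsReport, metrics

#: (mode, stratum) -> dict of class counts and the published 2-dp metrics
REFERENCE_TABLE: dict[tuple[str, str], dict] = {
    ("strict", "all"): dict(nn=1612, pp=870, np=127, total=2609,
                            sensitivity=0.93, specificity=0.96, accuracy=0.95, mcc=0.89),
    ("strict", ">0.3"): dict(nn=632, pp=823, np=30, total=1485,
                             sensitivity=0.98, specificity=0.98, accuracy=0.98, mcc=0.96),
    ("similar_mut", "all"): dict(nn=2164, pp=1433, np=178, total=3775,
                                 sensitivity=0.94, specificity=0.96, accuracy=0.95, mcc=0.90),
    ("similar_mut", ">0.3"): dict(nn=909, pp=1376, np=60, total=2345,
                                  sensitivity=0.98, specificity=0.97, accuracy=0.97, mcc=0.95),
    ("similar_ref", "all"): dict(nn=1650, pp=872, np=150, total=2672,
                                 sensitivity=0.92, specificity=0.96, accuracy=0.94, mcc=0.88),
    ("similar_ref", ">0.3"): dict(nn=556, pp=824, np=33, total=1413,
                                  sensitivity=0.98, specificity=0.97, accuracy=0.98, mcc=0.95),
    ("similar_both", "all"): dict(nn=3074, pp=1444, np=266, total=4784,
                                  sensitivity=0.92, specificity=0.96, accuracy=0.94, mcc=0.87),
    ("similar_both", ">0.3"): dict(nn=1083, pp=1381, np=89, total=2553,
                                   sensitivity=0.97, specificity=0.96, accuracy=0.97, mcc=0.93),
}


def reference_confusion(mode: str, stratum: str) -> ConfusionCounts:
    row = REFERENCE_TABLE[(mode, stratum)]
    return ConfusionCounts(pp_pairs=row["pp"], nn_pairs=row["nn"], np_pairs=row["np"])


def reference_metrics(mode: str, stratum: str) -> MetricsReport:
    return metrics(reference_confusion(mode, stratum))
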