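"""Published pan-cancer cohort sizes used as worked-example inputs.

A widely used curation of TCGA whole-exome/whole-genome studies spans 27
cancer types with 7434 tumor samples in total; per cohort it reports the
number of samples, the total number of somatic mutations, and the mean
mutation burden per sample rounded to two decimals. The (samples, mutations)
pairs below are those printed cohort sizes; they serve as inputs for the
synthetic cohort generator and as ground truth for the cohort-summary
arithmetic in :func:`drivercall.maf_io.summarize_cohort`.
"""

from __future__ import annotations

__all__ = ["PANCANCER_COHORTS", "pancancer_total_samples"]

#: cancer-type abbreviation -> (n_samples, n_mutations)
PANCANCER_COHORTS: dict[str, tuple[int, int]] = {
    "BLCA": (142, 33772),
    "BRCA": (889, 51766),
    "CESC": (38, 6115),
    "CLL": (224, 3491),
    "COAD": (244, 32192),
    "DLBCL": (57, 5785),
    "ESCA": (160, 19141),
    "GBM": (365, 21923),
    "HNSC": (407, 60074),
    "KIRC": (484, 28483),
    "KIRP": (112, 7541),
    "LAML": (197, 4180),
    "LIHC": (151, 7648),
    "LGG": (227, 9965),
    "LUAD": (394, 106613),
    "LUSC": (175, 53528),
    "MB": (332, 3615),
    "MESO": (289, 97806),
    "MM": (205, 10781),
    "NBL": (352, 6453),
    "OV": (480, 28136),
    "PAAD": (234, 7939),
    "PRAD": (420, 16784),
    "STAD": (244, 42456),
    "SCLC": (31, 8378),
    "THCA": (326, 6424),
    "UCEC": (255, 39234),
}


def pancancer_total_samples() -> int:
    """Sum of sample counts across the 27 cohorts."""
    return sum(s for s, _ in PANCANCER_COHORTS.values())
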