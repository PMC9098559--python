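"""Study-design constants of the developmental cohort analysis.

These record the sampling frame, exclusion cascade, acquisition facts and
analysis settings of the cross-sectional youth cohort (ages 8-23) that the
pipeline is designed around.  They are plain design facts, kept in one place
so that derived quantities (final sample size, pooled group-matrix shape,
scan duration, number of network scales) are always computed rather than
hard-coded at call sites.
"""

from __future__ import annotations

# --- participant exclusion cascade -------------------------------------------
N_RECRUITED = 1601
N_EXCLUDED_CLINICAL = 340   # psychoactive medication, inpatient history, structural anomaly
N_EXCLUDED_T1 = 54          # low-quality T1 / surface reconstruction
N_EXCLUDED_FUNCTIONAL = 514  # missing or low-quality functional runs

# --- acquisition facts --------------------------------------------------------
TR_SECONDS = 3.0
RUN_VOLUMES_RAW = (124, 231, 210)   # rest, n-back, emotion identification (as acquired)
# Concatenated analysable volumes after removal of initial volumes of each run:
CONCATENATED_VOLUMES = 555

# --- analysis settings --------------------------------------------------------
K_MIN = 2
K_MAX = 30
GROUP_BOOTSTRAP_SUBJECTS = 100  # subjects per group-decomposition bootstrap
GROUP_BOOTSTRAP_REPS = 50
AGE_RANGE_YEARS = (8.0, 23.0)
NMF_ALPHA = 1.0   # consensus ("sparsity") weight
NMF_BETA = 10.0   # locality weight


def final_sample_size() -> int:
    """Participants surviving the full exclusion cascade."""
    return N_RECRUITED - N_EXCLUDED_CLINICAL - N_EXCLUDED_T1 - N_EXCLUDED_FUNCTIONAL


def concatenated_duration_seconds() -> float:
    """Total usable scan duration per subject, seconds."""
    return CONCATENATED_VOLUMES * TR_SECONDS


def group_matrix_rows(n_subjects: int = GROUP_BOOTSTRAP_SUBJECTS) -> int:
    """Row count of the temporally concatenated group matrix."""
    return n_subjects * CONCATENATED_VOLUMES


def n_scales(k_min: int = K_MIN, k_max: int = K_MAX) -> int:
    """Number of network resolutions in the scale sweep."""
    return k_max - k_min + 1
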