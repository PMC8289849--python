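"""Shared constants and small utilities for the test suite."""

from pathlib import Path

#: a scaled-down cohort that still satisfies every generator feasibility
#: constraint (bridging families need >= 4 PD blood and >= 2 PD CSF samples,
#: the largest non-bridging family needs 4 distinct HC blood samples)
SMALL = dict(
    n_pd_blood=4,
    n_hc_blood=4,
    n_pd_csf=2,
    n_hc_csf=2,
    cells_per_blood_sample=120,
    cells_per_csf_sample=60,
)


def tree_files(root) -> list[str]:
    """Sorted relative paths of all files under ``root``."""
    root = Path(root)
    return sorted(str(p.relative_to(root)) for p in root.rglob("*") if p.is_file())
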