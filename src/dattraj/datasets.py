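"""Small packaged example tables (all synthetic, generated by hand)."""

from __future__ import annotations

from importlib import resources

from .io_cohort import Cohort, read_cohort


def load_exclusion_toy() -> Cohort:
    """Synthetic 10-subject PD table exercising the exclusion rule.

    Two subjects (S03, S07) are constructed to satisfy both exclusion
    conditions against a control group with mean putaminal SBR 2.13 and
    SD 0.55 (threshold 1.58): a more-affected baseline above the
    threshold together with a positive annual change rate.
    """
    ref = resources.files("dattraj") / "data" / "exclusion_toy.csv"
    with resources.as_file(ref) as path:
        return read_cohort(path, metadata={"source": "dattraj packaged toy"})
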