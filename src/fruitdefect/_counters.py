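"""Global call counters used to audit computational economy.

The pipeline's efficiency argument rests on doing expensive steps (HSV
conversion, Otsu threshold computation) as few times as possible, so those
steps increment a process-wide counter that tests and the pipeline log can
inspect.
"""

from collections import Counter

counters: Counter = Counter()


def reset_counters() -> None:
    """Zero every counter (typically at the start of a pipeline run or test)."""
    counters.clear()


def snapshot() -> dict:
    """Return a plain-dict copy of the current counter state."""
    return dict(counters)
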