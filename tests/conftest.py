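"""Shared fixtures.

The two 2 Mb recovery runs (with sequencing errors, and error-free) are the
canonical study conditions for the end-to-end benchmarks; they are
session-scoped because each takes a few minutes on one CPU.
"""
from __future__ import annotations

import pytest

from refscaf.pipeline import RecoveryResult, run_recovery

RECOVERY_SEED = 1


@pytest.fixture(scope="session")
def recovery_run() -> RecoveryResult:
    """Full pipeline on the canonical 2 Mb simulation (1% base errors)."""
    return run_recovery(seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_run_errorfree() -> RecoveryResult:
    """Same study conditions re-simulated with error-free reads."""
    return run_recovery(seed=RECOVERY_SEED, base_error_rate=0.0)
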