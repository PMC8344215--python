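#!/usr/bin/env python
"""One-shot reproduction of every in-scope number from the bundled fixtures.

Runs the full pipeline (comparisons, ancestral inference, event detection,
census tables, t-tests), verifies each headline number against its
published value and writes the complete report bundle to results/report/.
Exits non-zero if any verification fails.
"""

import sys

from lousemito.pipeline import run_reproduce


def main() -> int:
    report = run_reproduce(outdir="results/report")
    print(report.summary_text())
    return 0 if report.ok else 1


if __name__ == "__main__":
    sys.exit(main())
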