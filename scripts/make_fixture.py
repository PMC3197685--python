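"""Regenerate the packaged 1-year data files.

Writes the built-in observed frequency tables and the reconstructed
patient-level cohort to ``src/clcounts/data/``.  Run from the repository
root after any change to the built-in tables:

    python scripts/make_fixture.py
"""

from pathlib import Path

import pandas as pd

from clcounts.data_io import (
    one_year_frequency_tables,
    reconstruct_one_year_cohort,
    write_counts,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "clcounts" / "data"


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in one_year_frequency_tables():
        for k, pct in t.rows:
            rows.append(
                {"arm": t.arm, "declared_n": t.declared_n,
                 "count_value": k, "observed_pct": pct}
            )
    freq_path = DATA_DIR / "one_year_frequencies.csv"
    pd.DataFrame(rows).to_csv(freq_path, index=False)
    print(f"wrote {freq_path}")

    counts_path = DATA_DIR / "one_year_counts.csv"
    records = reconstruct_one_year_cohort()
    write_counts(records, counts_path)
    print(f"wrote {counts_path} ({len(records)} records)")


if __name__ == "__main__":
    main()
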