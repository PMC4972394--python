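#!/usr/bin/env python
"""Generate the synthetic demographic input bundle.

Writes births.csv (1940-1960), lifetable.csv (1946-2012, mirroring the
availability window of detailed official period tables), infant.csv
(age-0 mortality for the 1940-1945 backfill), and the six scenario
YAMLs to results/inputs/. Prints the life expectancies implied by the
synthetic mortality surface as a plausibility check.
"""

from pathlib import Path

import arfvhd as av

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    params = av.SyntheticDemographyParams()
    av.make_fixture_bundle(OUT, params)
    print(f"wrote input bundle to {OUT}")

    table = av.make_life_table(params)
    print("\nperiod life expectancy at birth (synthetic surface):")
    for year in (1940, 1960, 1990, 2012):
        e0 = {s: av.life_expectancy_at_birth(table, year, s) for s in ("male", "female")}
        print(f"  {year}: male {e0['male']:5.1f} y   female {e0['female']:5.1f} y")


if __name__ == "__main__":
    main()
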