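#!/usr/bin/env python
"""Validate the cohort engine and the conditional-probability formula
against the individual-level Monte-Carlo simulator.

Simulates 100,000 life courses under scenario 1a, compares the 2013
state fractions with the deterministic expectations, and checks the
empirical P(ARF-VHD | VHD and exposure) against prevalence / p.
Writes results/microsim_check.json.
"""

import json
import math
from pathlib import Path

import arfvhd as av

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "run_cohort_model", Path(__file__).with_name("02_run_cohort_model.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_inputs = _mod.load_inputs


def main(n: int = 100_000, seed: int = 42) -> None:
    births, table = load_inputs()
    scenario = av.default_scenarios()[0]
    cfg = av.MicrosimConfig(
        n_individuals=n, seed=seed, births=births, life_table=table, scenario=scenario
    )
    res = av.microsimulate(cfg)
    det = av.run_model(res.allocation, table, scenario)
    fs = det.final_states()

    report = {"n": n, "seed": seed, "scenario": "scenario1a", "states": {}}
    print(f"microsim n={n:,} vs deterministic engine (z = diff / binomial SE):")
    for state in ("arf_free", "post_arf_no_vhd", "arf_vhd", "dead"):
        expected = fs[state].sum() / n
        empirical = res.state_counts[state] / n
        se = math.sqrt(max(expected * (1 - expected), 1e-12) / n)
        z = (empirical - expected) / se
        report["states"][state] = {"empirical": empirical, "expected": expected, "z": z}
        print(f"  {state:16s} emp {empirical:.5f}  exp {expected:.5f}  z {z:+.2f}")

    formula = av.conditional_probability(
        av.prevalence_final_year(det), cfg.p_vhd_given_benfluorex
    )
    z = (res.p_arf_vhd_given_vhd_exposed - formula) / res.p_arf_vhd_given_vhd_exposed_se
    report["conditional_probability"] = {
        "formula": formula,
        "empirical": res.p_arf_vhd_given_vhd_exposed,
        "se": res.p_arf_vhd_given_vhd_exposed_se,
        "z": z,
    }
    print(
        f"  P(ARF-VHD | VHD & exposed): formula {formula:.5f}  "
        f"empirical {res.p_arf_vhd_given_vhd_exposed:.5f} "
        f"(SE {res.p_arf_vhd_given_vhd_exposed_se:.5f}, z {z:+.2f})"
    )

    OUT.mkdir(exist_ok=True)
    (OUT / "microsim_check.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT / 'microsim_check.json'}")


if __name__ == "__main__":
    main()
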