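"""Build the deterministic 217-patient registry fixture and write it to CSV.

The fixture encodes the published group-level cohort structure — 4 centres,
experience groups of 40/40/137 patients, major complications 4/3/4 and poor
outcomes 3/1/1 per group, with component complication columns — so every
downstream stage can be exercised without access to patient-level data.
"""

from pathlib import Path

import lcurve as lc

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    fx = lc.build_plus_fixture()
    lc.write_cases(fx, OUT / "fixture_cases.csv")
    print(f"wrote {len(fx)} cases to {OUT / 'fixture_cases.csv'}")
    print("\nevents by experience group:")
    cols = ["major_complication", "poor_outcome", "haemorrhagic_event",
            "ischaemic_event", "mass_effect"]
    print(fx.groupby("experience_group")[cols].sum().to_string())


if __name__ == "__main__":
    main()
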