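# File formats

## Canonical sensorgram CSV

Long format, one row per sample; header is case- and order-insensitive:

| column             | meaning                                        |
|--------------------|------------------------------------------------|
| `curve_id`         | label, unique per curve                        |
| `phase`            | `association` or `dissociation`                |
| `time_s`           | phase-local time, seconds, strictly increasing |
| `signal`           | instrument response (arbitrary linear units)   |
| `concentration_uM` | analyte concentration, μM, constant per curve  |

Every curve must have both phases with at least 4 samples each. Times
carried on a global experiment clock (a phase starting after 0) are
re-zeroed to the phase-local origin on read, with a log notice.
Concentrations are always μM — no unit auto-detection.

## Converting a wide vendor export

Instrument software typically exports one time column plus one signal
column per sensor, with phase boundaries given separately. A minimal
pandas recipe:

```python
import pandas as pd

wide = pd.read_csv("export.csv")          # columns: Time, A1, A2, ...
concs = {"A1": 8.0, "A2": 4.0, "A3": 0.0}  # μM per sensor column
assoc_start, dissoc_start, dissoc_end = 0.0, 300.0, 600.0

rows = []
for col, conc in concs.items():
    for phase, lo, hi in [("association", assoc_start, dissoc_start),
                          ("dissociation", dissoc_start, dissoc_end)]:
        block = wide[(wide.Time >= lo) & (wide.Time < hi)]
        rows.append(pd.DataFrame({
            "curve_id": col, "phase": phase,
            "time_s": block.Time - lo,          # phase-local
            "signal": block[col], "concentration_uM": conc,
        }))
pd.concat(rows).to_csv("sensorgrams.csv", index=False)
```

## Fit reports

`blifit fit` / `blifit profile` write JSON (full precision, bit-stable for
identical inputs, the round-trip master format); `write_report(...,
format="csv")` flattens the same fields to columns plus rounded
`*_display` strings following the `best ± half-width` convention (the
half-width rounded to one significant digit). Every CLI output is
accompanied by a `<output>.manifest.json` recording the command, package
version, resolved parameters, and SHA-256 digests of the inputs.
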