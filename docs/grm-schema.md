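# GRM JSON schema (version 1)

A gene regulatory mechanism is stored as a single JSON object. Floats
round-trip bit-exactly (repr-based encoding). `grmdesign.from_json` /
`to_json` read and write this format and validate every structural
invariant on load.

```json
{
  "version": 1,
  "genes": [
    {
      "name": "red",
      "role": "input",
      "production": 0.0,
      "decay": 0.0,
      "diffusion": 0.0,
      "orientation": "from_top",
      "gradient_decay": 0.93
    },
    {
      "name": "a",
      "role": "intermediate",
      "production": 0.0821,
      "decay": 0.475,
      "diffusion": 0.0
    },
    {
      "name": "blue",
      "role": "reporter",
      "production": 0.0993,
      "decay": 0.101,
      "diffusion": 0.0
    }
  ],
  "regulations": [
    {
      "source": "red",
      "target": "blue",
      "sign": "negative",
      "grouping": "necessary",
      "hill_coeff": 8.4,
      "bind_const": 3.1
    }
  ],
  "reporter_bindings": {"blue": 0}
}
```

## Fields

### genes[]

| field | type | constraints |
|---|---|---|
| `name` | string | unique within the file |
| `role` | string | `input`, `intermediate`, or `reporter` |
| `production` | number | >= 0; must be 0 for inputs |
| `decay` | number | >= 0 (1/time) |
| `diffusion` | number | >= 0; 0 throughout this work |
| `orientation` | string | inputs only: `from_left`, `from_top`, `from_right`, `from_bottom` |
| `gradient_decay` | number | inputs only: gradient base d in (0, 1), default 0.93 |

Basal expression is **derived**, not stored: 0 if the gene has at
least one positive regulation, else 1.

### regulations[]

| field | type | constraints |
|---|---|---|
| `source` | string | existing gene name; never a reporter |
| `target` | string | existing gene name; never an input |
| `sign` | string | `positive` or `negative` |
| `grouping` | string | `necessary` or `sufficient`; negative regulations are always `necessary` |
| `hill_coeff` | number | in [1, 10] |
| `bind_const` | number | in [1, 100] |

At most one regulation per ordered (source, target) pair.

### reporter_bindings

Object mapping each reporter gene name to the 0-based index of the
target-pattern channel it is scored against.

## Errors

Missing or ill-typed fields raise a parse error naming the field
(`GRMParseError`); well-formed files violating a structural invariant
raise `GRMValidationError` listing every violation.
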