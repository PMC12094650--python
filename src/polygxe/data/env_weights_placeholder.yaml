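# PLACEHOLDER weight table. These log relative-risk weights are illustrative
# defaults for testing and synthetic demonstrations only; they are NOT the
# published instrument weights. Substantive analyses must override this file
# with the instrument's own domain/level weights.
source_note: "synthetic placeholder weights; non-canonical"
domains:
  - name: paternal_age
    reference: 0
    note: "advanced paternal age at birth (binary indicator)"
    levels:
      - {level: 0, weight: 0.0}
      - {level: 1, weight: 0.262}
  - name: pses
    reference: 0
    note: "low parental socioeconomic status"
    levels:
      - {level: 0, weight: 0.0}
      - {level: 1, weight: 0.470}
  - name: obstetric_complications
    reference: 0
    note: "history of obstetric complications"
    levels:
      - {level: 0, weight: 0.0}
      - {level: 1, weight: 0.336}
  - name: urbanicity
    reference: 0
    note: "urban upbringing"
    levels:
      - {level: 0, weight: 0.0}
      - {level: 1, weight: 0.182}
  - name: childhood_adversity
    reference: 0
    note: "significant childhood adversity"
    levels:
      - {level: 0, weight: 0.0}
      - {level: 1, weight: 0.693}
  - name: recent_life_events
    reference: 0
    note: "stressful recent life events"
    levels:
      - {level: 0, weight: 0.0}
      - {level: 1, weight: 0.405}
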