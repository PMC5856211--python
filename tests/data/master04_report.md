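# MTB report — MASTER-04-like

## Patient information

- Cancer type: ovarian cancer
- SNVs/indels: 2 (1 silent)
- CNVs: 2 (1 high-level)
- Fusions: 0

## Gene–drug predictive associations

Associations are ranked by drug support, evidence level (A1 > B1 > A2 > B2 > A3 > B3) and gene. Association semantics: response = green, resistance = red; variants of unknown significance (repurposed) = gray.

Associations per level — A2: 1, B2: 3, A3: 1

| Gene | Patient variant | Known variant | Cancer type | Drug | Association | Level | Significance |
|---|---|---|---|---|---|---|---|
| TSC2 | TSC2 stopgain (R505X) | any_inactivating | kidney cancer | mTOR inhibitor | response | B2a | repurposed |
| TSC2 | TSC2 stopgain (R505X) | any_inactivating | breast cancer | mTOR inhibitor | response | B2b | repurposed |
| TSC2 | TSC2 stopgain (R505X) | any_inactivating | ovarian cancer | mTOR inhibitor | response | A3 | repurposed |
| CCND1 | CCND1 high_amplification | amplification | breast cancer | CDK4/6 inhibitor | response | B2a | known |
| CCND1 | CCND1 high_amplification | amplification | ovarian cancer | examplinib | resistance | A2c | known |

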