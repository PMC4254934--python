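ASHW001: ASHW
ASHW002: ASHW
ASHW003: ASHW
ASHW004: ASHW
ASHW005: ASHW
ASHW006: ASHW
ASHW007: ASHW
ASHW008: ASHW
ASHW009: ASHW
ASHW010: ASHW
ASHW011: ASHW
ASHW012: ASHW
ASHW013: ASHW
ASHW014: ASHW
ASHW015: ASHW
ASHW016: ASHW
ASHW017: ASHW
ASHW018: ASHW
ASHW019: ASHW
ASHW020: ASHW
ASHW021: ASHW
ASHW022: ASHW
ASHW023: ASHW
ASHW024: ASHW
ASHW025: ASHW
ASHW026: ASHW
ASHW027: ASHW
ASHW028: ASHW
ASHW029: ASHW
ASHW030: ASHW
ASHW031: ASHW
ASHW032: ASHW
ASHW033: ASHW
ASHW034: ASHW
ASHW035: ASHW
ASHW036: ASHW
ASHW037: ASHW
ASHW038: ASHW
ASHW039: ASHW
ASHW040: ASHW
ASHW041: ASHW
ASHW042: ASHW
ASHW043: ASHW
ASHW044: ASHW
ASHW045: ASHW
ASHW046: ASHW
ASHW047: ASHW
ASHWdup01: ASHW
ASHWdup02: ASHW
ASHWdup03: ASHW
ASHWdup04: ASHW
ASHWdup05: ASHW
ASHWdup06: ASHW
ASHWdup07: ASHW
ASHWdup08: ASHW
ASHWdup09: ASHW
ASHWdup10: ASHW
ASHWdup11: ASHW
ASHWdup12: ASHW
ASHWdup13: ASHW
ASHWdup14: ASHW
ASHWdup15: ASHW
ASHWdup16: ASHW
ASHWfail01: ASHW
ASHWfail02: ASHW
ASHWfail03: ASHW
ASHWfail04: ASHW
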