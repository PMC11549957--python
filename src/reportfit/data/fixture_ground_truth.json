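{
  "planted": {
    "cat00": [
      "sig00x00",
      "sig00x01",
      "sig00x02",
      "sig00x03",
      "sig00x04",
      "sig00x05",
      "sig00x06",
      "sig00x07",
      "sig00x08",
      "sig00x09"
    ],
    "cat01": [
      "sig01x00",
      "sig01x01",
      "sig01x02",
      "sig01x03",
      "sig01x04",
      "sig01x05",
      "sig01x06",
      "sig01x07",
      "sig01x08",
      "sig01x09"
    ],
    "cat02": [
      "sig02x00",
      "sig02x01",
      "sig02x02",
      "sig02x03",
      "sig02x04",
      "sig02x05",
      "sig02x06",
      "sig02x07",
      "sig02x08",
      "sig02x09"
    ],
    "cat03": [
      "sig03x00",
      "sig03x01",
      "sig03x02",
      "sig03x03",
      "sig03x04",
      "sig03x05",
      "sig03x06",
      "sig03x07",
      "sig03x08",
      "sig03x09"
    ]
  },
  "config": {
    "n_categories": 4,
    "reports_per_category": 10,
    "sentences_per_report_mean": 3.0,
    "min_sentences": 1,
    "tokens_per_sentence_mean": 8.0,
    "min_tokens": 3,
    "shared_vocab_size": 300,
    "signal_tokens_per_category": 10,
    "signal_boost": 20.0,
    "zipf_exponent": 0.3,
    "seed": 20240901
  }
}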