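{
  "decks": [
    {"label": "A", "gain": 100.0, "loss_magnitude": 1250.0, "loss_prob": 0.1, "advantageous": true},
    {"label": "B", "gain": 100.0, "loss_magnitude": 250.0, "loss_prob": 0.5, "advantageous": true},
    {"label": "C", "gain": 50.0, "loss_magnitude": 50.0, "loss_prob": 0.5, "advantageous": false},
    {"label": "D", "gain": 50.0, "loss_magnitude": 250.0, "loss_prob": 0.1, "advantageous": false}
  ],
  "n_trials": 100,
  "block_size": 20,
  "normalizer": 100.0
}
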