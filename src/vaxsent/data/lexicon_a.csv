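token,valence
good,0.7
great,0.8
amazing,0.9
hope,0.6
hopeful,0.7
effective,0.6
safe,0.5
breakthrough,0.8
success,0.7
successful,0.7
relief,0.6
optimistic,0.7
progress,0.5
protect,0.4
protection,0.4
bad,-0.7
fear,-0.6
scared,-0.7
unsafe,-0.6
dangerous,-0.7
hoax,-0.8
conspiracy,-0.8
risk,-0.4
risky,-0.5
worried,-0.5
misinformation,-0.6
distrust,-0.7
refuse,-0.5
harm,-0.6
rushed,-0.5
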