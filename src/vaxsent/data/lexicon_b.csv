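token,valence
good,0.6
great,0.8
amazing,1.0
hope,0.5
hopeful,0.6
effective,0.7
safe,0.6
breakthrough,0.7
success,0.8
successful,0.8
relief,0.5
optimistic,0.8
progress,0.4
protect,0.5
protection,0.5
bad,-0.6
fear,-0.7
scared,-0.6
unsafe,-0.7
dangerous,-0.8
hoax,-0.9
conspiracy,-0.7
risk,-0.3
risky,-0.6
worried,-0.6
misinformation,-0.7
distrust,-0.6
refuse,-0.4
harm,-0.7
rushed,-0.4
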