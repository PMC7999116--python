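segment,cutoff_pct,region,threshold_mm,youden_j,secondary_mm,secondary_youden_j,auc
maxilla,30,nasopharynx,5.5,0.478,,,0.702
maxilla,30,oropharynx,6.6,0.287,,,0.629
maxilla,30,hypopharynx,4.8,0.477,,,0.700
maxilla,50,nasopharynx,5.5,0.614,,,0.766
maxilla,50,oropharynx,6.6,0.391,,,0.677
maxilla,50,hypopharynx,4.8,0.599,,,0.753
maxilla,100,nasopharynx,6.6,0.815,,,0.890
maxilla,100,oropharynx,7.0,0.597,,,0.735
maxilla,100,hypopharynx,4.8,0.566,,,0.728
mandible,30,nasopharynx,5.2,0.380,1.4,0.407,0.723
mandible,30,oropharynx,5.2,0.384,,,0.687
mandible,30,hypopharynx,5.9,0.494,,,0.746
mandible,50,nasopharynx,5.2,0.496,1.4,0.520,0.785
mandible,50,oropharynx,5.2,0.557,,,0.805
mandible,50,hypopharynx,5.9,0.596,,,0.826
mandible,100,nasopharynx,5.2,0.630,,,0.810
mandible,100,oropharynx,5.2,0.751,,,0.935
mandible,100,hypopharynx,6.2,0.776,,,0.902
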