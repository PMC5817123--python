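tank_id,x1,x2,y1,y2,y3
sol,0,0,0.03406,-0.1553,-0.09257
g1,1,1,-0.5806,-0.4746,-0.2221
g2,1,1,-0.5857,0.6918,-0.4554
g3,2,3,-0.8611,1.4240,-1.3146
g4,2,3,-0.5991,0.3082,-1.7123
g5,1,4,-0.8153,1.7225,-0.9942
g6,3,5,-0.8441,2.1265,-1.1261
g7,3,6,-0.8320,1.1593,-1.3087
g8,6,7,-0.8861,1.1094,-0.6786
g9,3,8,-0.6765,1.5385,-1.6399
g10,3,9,-0.9165,1.3551,-1.1827
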