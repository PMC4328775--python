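category,generation,site,mean_count
I,2009,1,6.6
I,2009,2,5.0
I,2009,3,13.6
I,2009,4,8.0
I,2009,5,4.6
I,2009,6,47.4
I,2009,7,24.1
I,2009,8,8.2
I,2010,1,37.9
I,2010,2,35.8
I,2010,3,21.5
I,2010,4,8.9
I,2010,5,1.5
I,2010,6,8.3
I,2010,7,6.4
I,2010,8,29.3
I,2011,1,14.9
I,2011,2,10.0
I,2011,3,6.0
I,2011,4,1.3
I,2011,5,0.3
I,2011,6,21.1
I,2011,7,20.3
I,2011,8,15.0
I,2012,1,0.4
I,2012,2,7.4
I,2012,3,3.7
I,2012,4,0.0
I,2012,5,0.1
I,2012,6,12.6
I,2012,7,16.8
I,2012,8,2.6
M,2009,1,0.0
M,2009,2,0.7
M,2009,3,0.1
M,2009,4,0.0
M,2009,5,0.0
M,2009,6,9.0
M,2009,7,3.8
M,2009,8,0.0
M,2010,1,8.7
M,2010,2,6.9
M,2010,3,3.9
M,2010,4,0.9
M,2010,5,1.7
M,2010,6,37.6
M,2010,7,16.5
M,2010,8,3.6
M,2011,1,37.6
M,2011,2,24.4
M,2011,3,10.4
M,2011,4,1.6
M,2011,5,3.6
M,2011,6,62.5
M,2011,7,18.0
M,2011,8,11.8
M,2012,1,34.5
M,2012,2,22.8
M,2012,3,14.5
M,2012,4,3.8
M,2012,5,5.2
M,2012,6,60.7
M,2012,7,18.1
M,2012,8,16.3
H,2009,1,0.2
H,2009,2,0.5
H,2009,3,0.4
H,2009,4,0.4
H,2009,5,0.2
H,2009,6,4.5
H,2009,7,6.3
H,2009,8,0.0
H,2010,1,8.6
H,2010,2,16.1
H,2010,3,20.5
H,2010,4,7.5
H,2010,5,2.6
H,2010,6,25.5
H,2010,7,17.9
H,2010,8,16.8
H,2011,1,33.6
H,2011,2,24.0
H,2011,3,22.5
H,2011,4,4.5
H,2011,5,2.0
H,2011,6,23.8
H,2011,7,22.1
H,2011,8,16.3
H,2012,1,29.5
H,2012,2,31.3
H,2012,3,15.1
H,2012,4,2.3
H,2012,5,5.5
H,2012,6,46.8
H,2012,7,24.3
H,2012,8,42.6
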