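sample_id,batch,activity
A1,A,12.70
A2,A,8.33
A3,A,15.48
A4,A,14.68
A5,A,15.08
A6,A,9.52
A7,A,15.08
A8,A,5.95
A9,A,7.54
A10,A,0
A11,A,0
A12,A,2.38
A13,A,0.79
A14,A,2.78
A15,A,0
A16,A,3.57
A17,A,-10.32
A18,A,-8.73
A19,A,-6.35
A20,A,-14.68
A21,A,25.00
A22,A,13.86
A23,A,30.72
A24,A,6.02
B1,B,1.87
B2,B,-2.25
B3,B,2.25
B4,B,17.23
B5,B,8.61
B6,B,-4.87
B7,B,20.60
B8,B,-7.12
B9,B,16.10
B10,B,-1.12
B11,B,-4.12
B12,B,-8.24
B13,B,-15.36
B14,B,-10.11
B15,B,-7.87
B16,B,-7.12
B17,B,-7.49
B18,B,-8.24
B19,B,-4.87
B20,B,-12.36
B21,B,-11.75
B22,B,-17.17
B23,B,-19.28
B24,B,-17.47
C1,C,15.58
C2,C,20.29
C3,C,20.29
C4,C,43.48
C5,C,35.14
C6,C,26.45
C7,C,22.46
C8,C,57.25
C9,C,25.36
C10,C,25.36
C11,C,29.35
C12,C,27.17
C13,C,27.54
C14,C,19.20
C15,C,27.17
C16,C,26.81
C17,C,21.38
C18,C,19.20
C19,C,19.20
C20,C,19.93
C21,C,17.17
C22,C,5.12
C23,C,2.41
C24,C,-7.23
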