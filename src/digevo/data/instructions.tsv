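code	name	operand	summary
a	nop-A	none	No operation; as a modifier selects AX / instruction-pointer; template letter A.
b	nop-B	none	No operation; as a modifier selects BX / read head; template letter B.
c	nop-C	none	No operation; as a modifier selects CX / write head; template letter C.
d	if-n-equ	register(BX)	Execute next instruction only if ?BX? differs from its complement register.
e	if-less	register(BX)	Execute next instruction only if ?BX? is less than its complement register.
f	if-label	template	Execute next instruction only if the most recently copied nops equal the complement of the template.
g	mov-head	head(IP)	Move ?IP? to the flow head position.
h	jmp-head	head(IP)	Advance ?IP? by the value in CX (modulo memory size).
i	get-head	head(IP)	Write the position of ?IP? into CX.
j	set-flow	register(CX)	Move the flow head to the position given by ?CX?.
k	shift-r	register(BX)	Shift ?BX? right by one bit.
l	shift-l	register(BX)	Shift ?BX? left by one bit (32-bit wrap).
m	inc	register(BX)	Increment ?BX?.
n	dec	register(BX)	Decrement ?BX?.
o	push	register(BX)	Push ?BX? onto the active stack.
p	pop	register(BX)	Pop the active stack into ?BX? (0 if empty).
q	swap-stk	none	Toggle the active stack.
r	swap	register(BX)	Swap ?BX? with its complement register.
s	add	register(BX)	?BX? = BX + CX (32-bit wrap).
t	sub	register(BX)	?BX? = BX - CX (32-bit wrap).
u	nand	register(BX)	?BX? = bitwise NAND of BX and CX.
v	h-copy	none	Copy one instruction from the read head to the write head (with copy-mutation), advance both heads.
w	h-alloc	none	Extend memory to twice genome length for the offspring; place the write head at the offspring region.
x	h-divide	none	Split off the offspring region as a new genome if allocated and enough sites were copied; reset the CPU.
y	IO	register(BX)	Output ?BX? for task checking, then load a fresh random 5-bit input into ?BX? and the input buffer.
z	h-search	template	Find the complement of the template (forward, wrapping); flow head to the end of the match, BX=distance, CX=label size; empty template: flow head to the next site.
A	nop-X	none	Null instruction: no operation, never a template letter or modifier.
B	send-msg	none	Send the pair (BX, CX) to the neighbor currently faced.
C	retrieve-msg	none	Pop the oldest queued message into (BX, CX); no-op when the queue is empty.
D	bcast1	none	Send the pair (BX, CX) to all eight nearest neighbors.
E	rotate-left-one	none	Rotate facing one unit anticlockwise.
F	rotate-right-one	none	Rotate facing one unit clockwise.
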